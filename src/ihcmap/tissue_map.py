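"""Tissue maps from 32-px micro-patches and the 65% informativeness rule.

The DS8 H&E canvas is gridded into 32x32 cells, each labeled Tissue,
Submucosa, Muscle or Background by the micro-patch classifier. A 224-px
analysis patch is kept when at most 65% of its area falls on non-informative
(Muscle/Background) cells — strictly more than 65% drops it. Kept grid
patches then act as landmarks for overlapping-patch expansion: shifted
copies at +/-20 px steps, 10 steps along each axis direction, each itself
subject to the 65% rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import NON_INFORMATIVE_CATEGORIES, TISSUE_CATEGORIES
from .contracts import SmallPatchClassifier
from .slide_io import RollCanvas

CELL = 32
PATCH = 224
KEEP_CUTOFF = 0.65
SHIFT_STEP = 20
N_SHIFTS = 10


@dataclass
class TissueMap:
    labels: np.ndarray  # (rows, cols) int indices into TISSUE_CATEGORIES
    canvas_shape: tuple[int, int]  # DS8 (H, W)
    cell: int = CELL
    _noninf: np.ndarray | None = field(default=None, repr=False)

    def category(self, i: int, j: int) -> str:
        return TISSUE_CATEGORIES[self.labels[i, j]]

    @property
    def noninformative_pixels(self) -> np.ndarray:
        """Per-pixel non-informative indicator on the DS8 canvas (cached)."""
        if self._noninf is None:
            noninf_idx = [TISSUE_CATEGORIES.index(c) for c in NON_INFORMATIVE_CATEGORIES]
            cellwise = np.isin(self.labels, noninf_idx)
            full = np.kron(cellwise, np.ones((self.cell, self.cell), dtype=bool))
            h, w = self.canvas_shape
            self._noninf = full[:h, :w]
        return self._noninf


@dataclass
class PatchRecord:
    x: int  # top-left, DS8 px
    y: int
    size: int = PATCH
    non_informative_fraction: float = 0.0
    keep: bool = True
    origin: str = "grid"  # grid | overlap
    parent: tuple[int, int] | None = None  # landmark (x, y) for overlap patches


def build_tissue_map(canvas: RollCanvas, classifier: SmallPatchClassifier) -> TissueMap:
    """Classify every 32-px block; partial edge blocks are padded with white."""
    if canvas.ds_factor != 8:
        raise ValueError("tissue maps are built on the DS8 canvas")
    h, w = canvas.shape
    rows, cols = -(-h // CELL), -(-w // CELL)
    padded = np.full((rows * CELL, cols * CELL, 3), 255, dtype=np.uint8)
    padded[:h, :w] = canvas.pixels
    labels = np.zeros((rows, cols), dtype=np.int8)
    for i in range(rows):
        for j in range(cols):
            block = padded[i * CELL : (i + 1) * CELL, j * CELL : (j + 1) * CELL]
            labels[i, j] = TISSUE_CATEGORIES.index(classifier(block))
    return TissueMap(labels, (h, w))


def informative_fraction(patch: PatchRecord, tmap: TissueMap) -> float:
    """Non-informative area fraction of the patch, area-weighted over cells."""
    h, w = tmap.canvas_shape
    if patch.x < 0 or patch.y < 0 or patch.x + patch.size > w or patch.y + patch.size > h:
        raise ValueError(f"patch at ({patch.x}, {patch.y}) extends outside the canvas")
    window = tmap.noninformative_pixels[patch.y : patch.y + patch.size, patch.x : patch.x + patch.size]
    return float(window.sum()) / patch.size**2


def keep_patch(patch: PatchRecord, tmap: TissueMap) -> bool:
    """More than 65% non-informative area drops the patch; exactly 65% keeps it."""
    return informative_fraction(patch, tmap) <= KEEP_CUTOFF


def grid_patches(canvas: RollCanvas, tmap: TissueMap) -> list[PatchRecord]:
    """Non-overlapping 224-px tiling from (0, 0); partial edge tiles discarded."""
    h, w = canvas.shape
    records = []
    for y in range(0, h - PATCH + 1, PATCH):
        for x in range(0, w - PATCH + 1, PATCH):
            rec = PatchRecord(x, y, origin="grid")
            rec.non_informative_fraction = informative_fraction(rec, tmap)
            rec.keep = rec.non_informative_fraction <= KEEP_CUTOFF
            records.append(rec)
    return records


def expand_overlapping(
    patch: PatchRecord,
    tmap: TissueMap,
    canvas_shape: tuple[int, int] | None = None,
    grid2d: bool = False,
) -> list[PatchRecord]:
    """Overlapping patches around a kept landmark.

    Default reading: single-axis shifts of +/-20·k px (k = 1..10) along each
    of up/down/left/right — at most 41 patches including the landmark.
    ``grid2d=True`` switches to the full 21x21 offset grid reading.
    """
    if not patch.keep:
        raise ValueError("overlap expansion starts from a kept landmark patch")
    h, w = canvas_shape or tmap.canvas_shape
    if grid2d:
        offsets = [
            (dx * SHIFT_STEP, dy * SHIFT_STEP)
            for dx in range(-N_SHIFTS, N_SHIFTS + 1)
            for dy in range(-N_SHIFTS, N_SHIFTS + 1)
        ]
    else:
        offsets = [(0, 0)]
        for k in range(1, N_SHIFTS + 1):
            offsets += [(k * SHIFT_STEP, 0), (-k * SHIFT_STEP, 0), (0, k * SHIFT_STEP), (0, -k * SHIFT_STEP)]
    out = []
    for dx, dy in offsets:
        x, y = patch.x + dx, patch.y + dy
        if x < 0 or y < 0 or x + patch.size > w or y + patch.size > h:
            continue
        rec = PatchRecord(
            x,
            y,
            size=patch.size,
            origin="grid" if (dx, dy) == (0, 0) else "overlap",
            parent=(patch.x, patch.y),
        )
        rec.non_informative_fraction = informative_fraction(rec, tmap)
        rec.keep = rec.non_informative_fraction <= KEEP_CUTOFF
        if rec.keep:
            if (dx, dy) == (0, 0):
                rec.origin = "grid"
                rec.non_informative_fraction = patch.non_informative_fraction
            out.append(rec)
    return out


def all_analysis_patches(canvas: RollCanvas, tmap: TissueMap, grid2d: bool = False) -> list[PatchRecord]:
    """Kept grid landmarks plus their kept overlapping expansions (deduplicated)."""
    kept = [p for p in grid_patches(canvas, tmap) if p.keep]
    out: list[PatchRecord] = []
    seen: set[tuple[int, int, str]] = set()
    for landmark in kept:
        for rec in expand_overlapping(landmark, tmap, grid2d=grid2d):
            key = (rec.x, rec.y, rec.origin)
            if key not in seen:
                seen.add(key)
                out.append(rec)
    return out
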