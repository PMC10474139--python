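"""DAB-positivity detection on IHC patches.

The detector follows a stain-physics route rather than a learned model:
optical-density color deconvolution with the standard hematoxylin-eosin-DAB
(Ruifrok-Johnston) stain matrix isolates the DAB channel; the channel is
mapped to 8-bit grayscale with a fixed gain, contrast enhanced and
thresholded; connected objects are filtered by a per-marker area window; and
dark hematoxylin crystal artifacts — which masquerade as strong DAB signal —
are excluded by intensity-thresholding the color-inverted RGB patch and
dropping any object that touches the artifact mask. Clumped cells are
intentionally counted as one connected object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box
from skimage.color import rgb2hed
from skimage.measure import label as cc_label
from skimage.measure import regionprops

#: fixed DAB-OD -> 8-bit gray gain; 765 puts the synthetic blob concentration
#: (~0.25) around gray 190 and keeps pale counterstain near zero.
DAB_GRAY_GAIN = 765.0


@dataclass
class MarkerConfig:
    """Per-marker detection parameters (the paper optimized these per marker
    but published no values; the defaults here are calibrated to the
    synthetic renderer and exposed in config)."""

    marker: str
    contrast_scale: float = 1.5
    dab_threshold: int = 120
    min_area: int = 30
    max_area: int = 1500
    artifact_threshold: int = 225
    connectivity: int = 8  # 4 or 8

    def __post_init__(self):
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if not (0 <= self.dab_threshold <= 255 and 0 <= self.artifact_threshold <= 255):
            raise ValueError("thresholds must lie in [0, 255]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class DetectionResult:
    x_ds2: int
    y_ds2: int
    marker: str
    object_count: int
    object_areas: list[int]
    artifact_count: int
    excluded_by_aggregate: bool = False
    clipped: bool = False
    positive_mask: np.ndarray | None = field(default=None, repr=False)
    artifact_mask: np.ndarray | None = field(default=None, repr=False)


def deconvolve_dab(patch: np.ndarray) -> np.ndarray:
    """Per-pixel DAB optical density via H-E-D color deconvolution."""
    arr = np.asarray(patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB patch")
    return rgb2hed(arr.astype(np.float64) / 255.0)[..., 2]


def make_positive_mask(dab_image: np.ndarray, config: MarkerConfig) -> np.ndarray:
    """Fixed-gain 8-bit grayscale, contrast enhancement, intensity threshold."""
    gray = np.clip(dab_image * DAB_GRAY_GAIN, 0, 255)
    enhanced = np.clip(gray * config.contrast_scale, 0, 255)
    return enhanced >= config.dab_threshold


def filter_by_size(mask: np.ndarray, config: MarkerConfig) -> tuple[np.ndarray, list]:
    """Label connected components and drop those outside the area window.

    Returns (labeled image with surviving labels only, surviving regionprops).
    """
    labeled = cc_label(mask, connectivity=config.skimage_connectivity)
    keep = [r for r in regionprops(labeled) if config.min_area <= r.area <= config.max_area]
    out = np.zeros_like(labeled)
    for r in keep:
        out[labeled == r.label] = r.label
    return out, keep


def exclude_crystal_artifacts(
    rgb_patch: np.ndarray, labeled: np.ndarray, objects: list, config: MarkerConfig
) -> tuple[list, list, np.ndarray]:
    """Drop objects that touch the inverted-space crystal-artifact mask.

    A pixel is artifact when every inverted channel (255 - RGB) is at or
    above the artifact threshold, i.e. the original pixel is near-black in
    all channels. Exclusion is by any-pixel overlap.
    """
    inverted = 255 - np.asarray(rgb_patch, dtype=np.int16)
    artifact_mask = inverted.min(axis=2) >= config.artifact_threshold
    retained, excluded = [], []
    for r in objects:
        if artifact_mask[labeled == r.label].any():
            excluded.append(r)
        else:
            retained.append(r)
    return retained, excluded, artifact_mask


def count_patch(rgb_patch: np.ndarray, config: MarkerConfig, keep_masks: bool = False) -> DetectionResult:
    """Full per-patch detection: deconvolve, threshold, size-filter, exclude
    crystal artifacts, count the remaining connected objects."""
    dab = deconvolve_dab(rgb_patch)
    mask = make_positive_mask(dab, config)
    labeled, objects = filter_by_size(mask, config)
    retained, excluded, artifact_mask = exclude_crystal_artifacts(rgb_patch, labeled, objects, config)
    retained_mask = np.isin(labeled, [r.label for r in retained]) if retained else np.zeros_like(mask)
    return DetectionResult(
        x_ds2=0,
        y_ds2=0,
        marker=config.marker,
        object_count=len(retained),
        object_areas=[int(r.area) for r in retained],
        artifact_count=len(excluded),
        positive_mask=retained_mask if keep_masks else None,
        artifact_mask=artifact_mask if keep_masks else None,
    )


def detect_roll(
    registered_canvas,
    kept_patch_coords_ds8: list[tuple[int, int]],
    config: MarkerConfig,
    aggregate_masks: list[np.ndarray] | None = None,
    patch_size_ds8: int = 224,
    keep_masks: bool = False,
    log: list | None = None,
) -> list[DetectionResult]:
    """Detect per H&E-guided window on a registered DS2 IHC canvas.

    Each kept DS8 H&E patch at (x, y) maps to the DS2 window
    [4x, 4x+896) x [4y, 4y+896). Windows overlapping a lymphoid-aggregate
    polygon by more than 10% area are flagged excluded and not counted;
    windows partially outside the canvas are clipped (with a warning) when at
    least half remains, else skipped.
    """
    pixels = registered_canvas.pixels
    h, w = pixels.shape[:2]
    size = patch_size_ds8 * 4
    aggregates = [Polygon(np.asarray(p, dtype=float)) for p in (aggregate_masks or [])]
    results = []
    for x8, y8 in kept_patch_coords_ds8:
        x, y = 4 * x8, 4 * y8
        win = box(x, y, x + size, y + size)
        agg_frac = sum(win.intersection(a).area for a in aggregates) / win.area
        if agg_frac > 0.10:
            results.append(
                DetectionResult(x, y, config.marker, 0, [], 0, excluded_by_aggregate=True)
            )
            continue
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + size, w), min(y + size, h)
        inside = (x1 - x0) * (y1 - y0) / (size * size)
        if inside < 0.5:
            if log is not None:
                log.append(f"window at ({x}, {y}) mostly outside canvas; skipped")
            continue
        patch = pixels[y0:y1, x0:x1]
        res = count_patch(patch, config, keep_masks=keep_masks)
        res.x_ds2, res.y_ds2 = x, y
        res.clipped = inside < 1.0
        if res.clipped and log is not None:
            log.append(f"window at ({x}, {y}) clipped to canvas")
        results.append(res)
    return results
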