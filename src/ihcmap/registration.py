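"""Iterative serial-section registration with mask-based QC.

Each section is registered onto its already-registered neighbor, so every
pairwise problem is between anatomically adjacent sections; composing down
the chain places all sections in the frame of the H&E reference (section 1).
QC is the Dice overlap between the registered section's tissue mask and the
H&E tissue mask — masks, not stain intensities, because the H&E and DAB
palettes differ.

The default engine estimates a rigid transform from the tissue masks: a
coarse-to-fine rotation scan scored by phase-correlation residual, followed
by subpixel translation via phase correlation. It is deterministic and
recovers the rigid warps the synthetic generator plants (|rot| <= 10 deg,
|t| <= 50 px) to well under a pixel. The engine is a pluggable contract;
any implementation whose output passes QC is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .slide_io import RollCanvas, _block_mean
from .transforms import AffineTransform2D, SpatialTransform

TISSUE_INTENSITY_CUTOFF = 235  # min channel below this => not near-white => tissue
DEFAULT_QC_THRESHOLD = 0.80


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, same frame as its canvas
    ds_factor: int = 2

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegistrationQC:
    section: int
    dice: float
    passed: bool
    threshold: float = DEFAULT_QC_THRESHOLD


class RegistrationError(RuntimeError):
    def __init__(self, message: str, completed: list | None = None):
        super().__init__(message)
        self.completed = completed or []


class RegistrationEngine(Protocol):
    def register(self, fixed: RollCanvas, moving: RollCanvas) -> SpatialTransform: ...


def compute_tissue_mask(canvas: RollCanvas) -> TissueMask:
    """Not-near-white pixels, morphologically closed, specks (<64 px) removed."""
    px = canvas.pixels
    tissue = np.minimum(np.minimum(px[..., 0], px[..., 1]), px[..., 2]) < TISSUE_INTENSITY_CUTOFF
    closed = ndimage.binary_closing(tissue, structure=disk(3), border_value=0)
    # drop connected components < 64 px (4-connectivity, as in remove_small_objects)
    lab, n = ndimage.label(closed)
    if n == 0:
        return TissueMask(closed, ds_factor=canvas.ds_factor)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= 64
    keep[0] = False
    return TissueMask(keep[lab], ds_factor=canvas.ds_factor)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _pad_to_multiple(arr: np.ndarray, f: int) -> np.ndarray:
    h, w = arr.shape
    return np.pad(arr, ((0, (-h) % f), (0, (-w) % f)))


class RigidMaskEngine:
    """Default rigid engine: rotation scan + subpixel phase correlation on masks."""

    def __init__(
        self,
        coarse_scale: int = 16,
        mid_scale: int = 8,
        refine_scale: int = 4,
        angle_range: float = 12.0,
        coarse_step: float = 1.0,
        fine_step: float = 0.1,
        upsample: int = 16,
    ):
        self.coarse_scale = coarse_scale
        self.mid_scale = mid_scale
        self.refine_scale = refine_scale
        self.angle_range = angle_range
        self.coarse_step = coarse_step
        self.fine_step = fine_step
        self.upsample = upsample

    @staticmethod
    def _score(fixed_fft: np.ndarray, rotated: np.ndarray) -> float:
        _, error, _ = phase_cross_correlation(
            fixed_fft, np.fft.fftn(rotated), space="fourier", normalization=None
        )
        return float(error)

    @staticmethod
    def _rotate(mask: np.ndarray, angle: float) -> np.ndarray:
        h, w = mask.shape
        t = AffineTransform2D.rigid(angle, center=(w / 2.0, h / 2.0))
        return t.warp_image(mask, order=1, cval=0.0)

    @staticmethod
    def _reduce(mask: np.ndarray, scale: int) -> np.ndarray:
        return _block_mean(_pad_to_multiple(mask, scale).astype(np.uint8) * 255, scale).astype(float)

    def register(self, fixed: RollCanvas, moving: RollCanvas) -> SpatialTransform:
        return self.register_masks(compute_tissue_mask(fixed).mask, compute_tissue_mask(moving).mask)

    def register_masks(self, fmask: np.ndarray, mmask: np.ndarray) -> SpatialTransform:
        """Estimate the rigid transform directly from boolean tissue masks."""
        if fmask.sum() == 0 or mmask.sum() == 0:
            raise RegistrationError("nothing to register: empty tissue mask")
        cs, ms, rs = self.coarse_scale, self.mid_scale, self.refine_scale

        def pyramid(mask):
            out = {rs: self._reduce(mask, rs)}
            for hi, lo in ((ms, rs), (cs, ms)):
                if hi % lo == 0:
                    out[hi] = _block_mean(out[lo].astype(np.uint8), hi // lo).astype(float)
                else:
                    out[hi] = self._reduce(mask, hi)
            return out

        fpyr, mpyr = pyramid(fmask), pyramid(mmask)
        f_c, m_c = fpyr[cs], mpyr[cs]
        f_c_fft = np.fft.fftn(f_c)
        angles = np.arange(-self.angle_range, self.angle_range + 1e-9, self.coarse_step)
        errs = [self._score(f_c_fft, self._rotate(m_c, a)) for a in angles]
        best = float(angles[int(np.argmin(errs))])

        f_m, m_m = fpyr[ms], mpyr[ms]
        f_m_fft = np.fft.fftn(f_m)
        fine = np.arange(best - self.coarse_step, best + self.coarse_step + 1e-9, self.fine_step)
        ferrs = [self._score(f_m_fft, self._rotate(m_m, a)) for a in fine]
        i = int(np.argmin(ferrs))
        theta = float(fine[i])
        if 0 < i < len(fine) - 1:  # parabolic sub-step refinement
            y0, y1, y2 = ferrs[i - 1], ferrs[i], ferrs[i + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                theta += self.fine_step * 0.5 * (y0 - y2) / denom

        f_r, m_r = fpyr[rs], mpyr[rs]
        hr, wr = m_r.shape
        rot_r = AffineTransform2D.rigid(theta, center=(wr / 2.0, hr / 2.0))
        rotated = rot_r.warp_image(m_r, order=1, cval=0.0)
        shift, _, _ = phase_cross_correlation(f_r, rotated, upsample_factor=self.upsample, normalization=None)
        tx, ty = float(shift[1]) * rs, float(shift[0]) * rs

        h, w = _pad_to_multiple(mmask, max(cs, rs)).shape
        return AffineTransform2D.rigid(theta, (tx, ty), center=(w / 2.0, h / 2.0))


def register_pair(
    fixed: RollCanvas, moving: RollCanvas, engine: RegistrationEngine | None = None
) -> SpatialTransform:
    if fixed.ds_factor != moving.ds_factor:
        raise ValueError("fixed and moving canvases must share a downsample factor")
    engine = engine or RigidMaskEngine()
    return engine.register(fixed, moving)


def register_stack(
    sections: list[RollCanvas],
    engine: RegistrationEngine | None = None,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> list[tuple[SpatialTransform, RegistrationQC]]:
    """Register sections 2..n iteratively onto their registered neighbor.

    Section 1 (H&E) is the reference and gets the identity; section k is
    registered onto section k-1 resampled into the reference frame, so the
    returned transform for each section maps it directly into the reference.
    On failure the chain aborts, reporting the completed sections.
    """
    engine = engine or RigidMaskEngine()
    he = sections[0]
    he_mask = compute_tissue_mask(he).mask
    results: list[tuple[SpatialTransform, RegistrationQC]] = [
        (AffineTransform2D.identity(), RegistrationQC(1, 1.0, True, qc_threshold))
    ]
    mask_chain = engine if isinstance(engine, RigidMaskEngine) else None
    prev_mask = he_mask  # previous section's tissue mask, in the reference frame
    prev_registered = he
    for k, section in enumerate(sections[1:], start=2):
        try:
            moving_mask = compute_tissue_mask(section).mask
            if mask_chain is not None:
                transform = mask_chain.register_masks(prev_mask, moving_mask)
            else:
                transform = register_pair(prev_registered, section, engine)
        except RegistrationError as exc:
            raise RegistrationError(f"registration failed at section {k}: {exc}", completed=results) from exc
        reg_mask = (
            transform.warp_image(moving_mask.astype(np.uint8), output_shape=he.shape, order=0, cval=0)
            .astype(bool)
        )
        d = dice_coefficient(he_mask, reg_mask)
        results.append((transform, RegistrationQC(k, d, d >= qc_threshold, qc_threshold)))
        prev_mask = reg_mask
        if mask_chain is None:
            reg_pixels = transform.warp_image(section.pixels, output_shape=he.shape, order=0, cval=255)
            prev_registered = RollCanvas(
                reg_pixels.astype(np.uint8), ds_factor=section.ds_factor, roll_id=section.roll_id
            )
    return results


def qc_overlay(he_canvas: RollCanvas, registered_mask: TissueMask) -> tuple[np.ndarray, RegistrationQC]:
    """H&E with a semi-transparent white fill where the registered mask is true."""
    if registered_mask.mask.shape != he_canvas.shape:
        raise ValueError("mask and canvas dimensions differ")
    overlay = he_canvas.pixels.astype(float).copy()
    m = registered_mask.mask
    overlay[m] = 0.5 * overlay[m] + 0.5 * 255.0
    he_mask = compute_tissue_mask(he_canvas).mask
    d = dice_coefficient(he_mask, registered_mask.mask)
    return overlay.astype(np.uint8), RegistrationQC(0, d, d >= DEFAULT_QC_THRESHOLD)


def select_analysis_roll(per_roll_qc: dict[int, list[RegistrationQC]]) -> int:
    """Pick the roll whose worst per-section dice is best; ties -> lowest index."""
    if not per_roll_qc:
        raise ValueError("no registered rolls to select from")
    best_idx, best_score = None, -1.0
    for idx in sorted(per_roll_qc):
        score = min(q.dice for q in per_roll_qc[idx])
        if score > best_score + 1e-12:
            best_idx, best_score = idx, score
    return best_idx
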