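"""Classifier contracts and their synthetic stand-ins.

The real pipeline plugs in trained CNN classifiers (a 32-px tissue-category
classifier and a 224-px disease classifier that doubles as a 512-d encoder).
Training and weights are out of scope here; the contracts below define the
interfaces, and the color-decoding stand-ins satisfy them exactly on
synthetic canvases whose zones carry the catalog color codes.
"""

from __future__ import annotations

import zlib
from typing import Protocol

import numpy as np

from .catalog import (
    ALL_CLASSES,
    CATEGORY_COLORS,
    CLASS_COLORS,
    INVOLVED_CLASSES,
    WHITE,
    class_color_array,
)

EMBED_DIM = 512


class SmallPatchClassifier(Protocol):
    """32x32 RGB micro-patch -> tissue category name. Deterministic."""

    def __call__(self, patch: np.ndarray) -> str: ...


class PatchClassifier(Protocol):
    """224-px H&E patch -> (p_involved, p_uninvolved) and a 512-d embedding."""

    def predict(self, patch: np.ndarray) -> tuple[float, float]: ...

    def embed(self, patch: np.ndarray) -> np.ndarray: ...


def _prototype_table() -> tuple[np.ndarray, list[str]]:
    colors, cats = [], []
    for cat in ("Background", "Muscle", "Submucosa"):
        colors.append(CATEGORY_COLORS[cat] if cat != "Background" else WHITE)
        cats.append(cat)
    for cls in ALL_CLASSES:
        colors.append(CLASS_COLORS[cls])
        cats.append("Tissue")
    return np.array(colors, dtype=float), cats


class ColorCodeSmallPatchClassifier:
    """Nearest-prototype decoder of the synthetic zone colors (mean RGB)."""

    def __init__(self):
        self._colors, self._cats = _prototype_table()

    def __call__(self, patch: np.ndarray) -> str:
        mean = np.asarray(patch, dtype=float).reshape(-1, 3).mean(axis=0)
        d = ((self._colors - mean) ** 2).sum(axis=1)
        return self._cats[int(np.argmin(d))]


_PROTO_COLORS, _PROTO_CATS = _prototype_table()
_PROTO_KEYS = (
    _PROTO_COLORS[:, 0].astype(np.int64) * 65536
    + _PROTO_COLORS[:, 1].astype(np.int64) * 256
    + _PROTO_COLORS[:, 2].astype(np.int64)
)
_KEY_ORDER = np.argsort(_PROTO_KEYS)


def _nearest_class_map(patch: np.ndarray) -> np.ndarray:
    """Per-pixel index into ALL_CLASSES, or -1 for non-class pixels.

    A pixel is attributed to a histology class only when it is closer to that
    class color than to white/muscle/submucosa (edge pixels mixed with the
    margin decode to the background prototypes and are ignored). Pixels that
    equal a palette color exactly — the overwhelming majority on synthetic
    canvases — take a hash-lookup fast path.
    """
    flat = np.asarray(patch).reshape(-1, 3)
    keys = flat[:, 0].astype(np.int64) * 65536 + flat[:, 1].astype(np.int64) * 256 + flat[:, 2].astype(np.int64)
    sorted_keys = _PROTO_KEYS[_KEY_ORDER]
    pos = np.searchsorted(sorted_keys, keys)
    pos = np.clip(pos, 0, len(sorted_keys) - 1)
    exact = sorted_keys[pos] == keys
    best = np.empty(len(flat), dtype=np.int64)
    best[exact] = _KEY_ORDER[pos[exact]]
    if (~exact).any():
        rest = flat[~exact].astype(float)
        d = ((rest[:, None, :] - _PROTO_COLORS[None, :, :]) ** 2).sum(axis=2)
        best[~exact] = np.argmin(d, axis=1)
    class_idx = best - 3  # first three prototypes are non-class
    class_idx[best < 3] = -1
    return class_idx


class ColorCodePatchClassifier:
    """Disease classifier stand-in: decodes planted class colors.

    ``predict`` returns the involved-pixel fraction among class-coded pixels;
    ``embed`` returns a near-one-hot 512-vector of the dominant class with a
    small jitter seeded from the patch content (deterministic per patch).
    """

    def __init__(self, jitter_scale: float = 0.1):
        self.jitter_scale = jitter_scale
        self._n_inv = len(INVOLVED_CLASSES)

    def predict(self, patch: np.ndarray) -> tuple[float, float]:
        cls = _nearest_class_map(patch)
        counts = np.bincount(cls[cls >= 0], minlength=len(ALL_CLASSES))
        inv = counts[: self._n_inv].sum()
        uninv = counts[self._n_inv :].sum()
        if inv + uninv == 0:
            return 0.0, 1.0
        p = float(inv) / float(inv + uninv)
        return p, 1.0 - p

    def embed(self, patch: np.ndarray) -> np.ndarray:
        cls = _nearest_class_map(patch)
        counts = np.bincount(cls[cls >= 0], minlength=len(ALL_CLASSES))
        dominant = int(counts.argmax()) if counts.sum() else 0
        vec = np.zeros(EMBED_DIM)
        block = EMBED_DIM // (len(ALL_CLASSES) + 1)
        vec[dominant * block : (dominant + 1) * block] = 10.0
        seed = zlib.crc32(np.ascontiguousarray(patch).tobytes()) & 0x7FFFFFFF
        rng = np.random.default_rng(seed)
        vec += rng.normal(0.0, self.jitter_scale, EMBED_DIM)
        return vec


def class_color_lookup() -> np.ndarray:
    return class_color_array()
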