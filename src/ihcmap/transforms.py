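"""Invertible, composable spatial transforms between section frames.

Coordinates are (x, y), 0-based, origin at the image top-left; a transform's
forward map takes points in the *moving* frame to the *fixed* (reference)
frame. Images are numpy arrays indexed [row=y, col=x].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SpatialTransform:
    """Abstract forward map (x, y) moving -> (x, y) fixed."""

    kind: str = "abstract"

    def apply(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inverse(self) -> "SpatialTransform":
        raise NotImplementedError

    def compose(self, inner: "SpatialTransform") -> "SpatialTransform":
        """Return T with T(x) = self(inner(x)). Associative."""
        if isinstance(self, AffineTransform2D) and isinstance(inner, AffineTransform2D):
            kind = "rigid" if self.kind == inner.kind == "rigid" else "affine"
            return AffineTransform2D(self.matrix @ inner.matrix, kind=kind)
        return CompositeTransform([inner, self])

    def warp_image(
        self,
        image: np.ndarray,
        output_shape: tuple[int, int] | None = None,
        order: int = 0,
        cval: float = 255,
        output_origin: tuple[int, int] = (0, 0),
    ) -> np.ndarray:
        """Resample ``image`` (moving frame) into the fixed frame.

        out(x_fixed) = image(T^{-1}(x_fixed)); out-of-domain pixels get cval.
        ``output_origin`` (x, y) renders only the fixed-frame window starting
        there, with the given shape.
        """
        inv = self.inverse()
        shape = output_shape or image.shape[:2]
        ox, oy = output_origin
        yy, xx = np.mgrid[oy : oy + shape[0], ox : ox + shape[1]]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
        src = inv.apply(pts)
        coords = np.stack([src[:, 1].reshape(shape), src[:, 0].reshape(shape)])
        if image.ndim == 2:
            return ndimage.map_coordinates(image, coords, order=order, cval=cval, mode="constant")
        chans = [
            ndimage.map_coordinates(image[..., c], coords, order=order, cval=cval, mode="constant")
            for c in range(image.shape[2])
        ]
        return np.stack(chans, axis=-1)

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class AffineTransform2D(SpatialTransform):
    """Affine forward map in homogeneous coordinates (3x3 matrix on (x, y, 1))."""

    matrix: np.ndarray
    kind: str = "affine"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3), kind="identity")

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        m = np.eye(3)
        m[0, 2], m[1, 2] = tx, ty
        return cls(m, kind="rigid")

    @classmethod
    def rigid(
        cls,
        rotation_deg: float,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Rotation about ``center`` followed by translation."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        cx, cy = center
        rot = np.array([[c, -s, cx - c * cx + s * cy], [s, c, cy - s * cx - c * cy], [0, 0, 1.0]])
        rot[0, 2] += translation[0]
        rot[1, 2] += translation[1]
        return cls(rot, kind="rigid")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2]

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix), kind=self.kind)

    # fast path: scipy affine resampling instead of explicit coordinate grids
    def warp_image(self, image, output_shape=None, order=0, cval=255, output_origin=(0, 0)):
        inv = np.linalg.inv(self.matrix)
        shape = output_shape or image.shape[:2]
        # (x, y) -> (row, col) conjugation
        swap = np.array([[0.0, 1.0], [1.0, 0.0]])
        a_rc = swap @ inv[:2, :2] @ swap
        off_rc = swap @ inv[:2, 2]
        if output_origin != (0, 0):
            o0 = np.array([output_origin[1], output_origin[0]], dtype=float)
            off_rc = a_rc @ o0 + off_rc

        def _one(chan):
            return ndimage.affine_transform(
                chan, a_rc, offset=off_rc, output_shape=shape, order=order, cval=cval, mode="constant"
            )

        if image.ndim == 2:
            return _one(image)
        return np.stack([_one(image[..., c]) for c in range(image.shape[2])], axis=-1)

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "matrix": self.matrix.tolist()}


@dataclass
class SinusoidalWarp(SpatialTransform):
    """Low-amplitude smooth warp: (x, y) -> (x + a·sin(2πy/λ), y + a·sin(2πx/λ)).

    Inverted by fixed-point iteration; for amplitudes well below λ/2π the map
    is a contraction and the round-trip error is far under 0.5 px.
    """

    amplitude: float
    period: float
    kind: str = field(default="deformable")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        w = 2 * np.pi / self.period
        out = pts.copy()
        out[:, 0] += self.amplitude * np.sin(w * pts[:, 1])
        out[:, 1] += self.amplitude * np.sin(w * pts[:, 0])
        return out

    def inverse(self) -> "SpatialTransform":
        return _InverseWarp(self)

    def to_dict(self) -> dict:
        return {"kind": "deformable", "amplitude": self.amplitude, "period": self.period}


@dataclass
class _InverseWarp(SpatialTransform):
    forward: SinusoidalWarp
    kind: str = field(default="deformable")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        x = pts.copy()
        for _ in range(25):
            x = pts - (self.forward.apply(x) - x)
        return x

    def inverse(self) -> SpatialTransform:
        return self.forward

    def to_dict(self) -> dict:
        return {"kind": "deformable-inverse", **self.forward.to_dict()}


@dataclass
class CompositeTransform(SpatialTransform):
    """Chain applied first-to-last: T(x) = parts[-1](... parts[0](x))."""

    parts: list
    kind: str = field(default="composite")

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(points, dtype=np.float64))
        for part in self.parts:
            out = part.apply(out)
        return out

    def inverse(self) -> "CompositeTransform":
        return CompositeTransform([p.inverse() for p in reversed(self.parts)])

    def to_dict(self) -> dict:
        return {"kind": "composite", "parts": [p.to_dict() for p in self.parts]}


def transform_from_dict(d: dict) -> SpatialTransform:
    kind = d["kind"]
    if kind == "composite":
        return CompositeTransform([transform_from_dict(p) for p in d["parts"]])
    if kind == "deformable":
        return SinusoidalWarp(d["amplitude"], d["period"])
    return AffineTransform2D(np.array(d["matrix"]), kind=kind)
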