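"""Slide loading, working resolutions and swiss-roll extraction.

The pipeline works at two downsample factors relative to the 40x scan
(0.17 um/px): DS2 for registration and IHC detection, DS8 for the H&E patch
classification. Individual swiss rolls are cropped along their annotation
polygon and pasted onto a white canvas whose dimensions are forced to be
divisible by 4, so the DS2 -> DS8 rescale is exact and the x4 coordinate
mapping between resolutions never accumulates rounding error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from shapely.geometry import Polygon

Image.MAX_IMAGE_PIXELS = None

VALID_DS = (1, 2, 8)


@dataclass
class SlidePlane:
    """One slide raster at a stated downsample factor."""

    pixels: np.ndarray  # (H, W, 3) uint8
    ds_factor: int
    source_id: str = ""

    def __post_init__(self):
        if self.pixels.size == 0:
            raise ValueError("empty slide raster")


@dataclass
class PolygonAnnotation:
    """Manual swiss-roll outline, DS2 coordinates, origin top-left."""

    vertices: np.ndarray  # (N, 2) of (x, y)
    roll_index: int = 1

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if poly.area == 0:
            raise ValueError("degenerate polygon (zero area)")
        if not poly.is_simple:
            raise ValueError("polygon is self-intersecting")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class RollCanvas:
    """One extracted swiss roll on a white canvas; the pipeline's coordinate frame."""

    pixels: np.ndarray  # (H, W, 3) uint8, white outside the roll
    ds_factor: int
    roll_id: str = ""
    crop_offset: tuple[int, int] = (0, 0)  # (x, y) of the crop origin in the parent plane
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    """Area-average downsample by integer factor; ceil dims, edge-replicated pad."""
    if f == 1:
        return img.copy()
    h, w = img.shape[:2]
    ph, pw = (-h) % f, (-w) % f
    pad = ((0, ph), (0, pw)) + ((0, 0),) * (img.ndim - 2)
    padded = np.pad(img, pad, mode="edge")
    hh, ww = padded.shape[0] // f, padded.shape[1] // f
    if np.issubdtype(padded.dtype, np.floating):
        if img.ndim == 2:
            out = padded.reshape(hh, f, ww, f).mean(axis=(1, 3))
        else:
            out = padded.reshape(hh, f, ww, f, img.shape[2]).mean(axis=(1, 3))
        return np.rint(out).astype(np.uint8)
    # integer block sums (uint32 holds f^2 * 255 for any working factor)
    if img.ndim == 2:
        sums = padded.reshape(hh, f, ww, f).sum(axis=(1, 3), dtype=np.uint32)
    else:
        sums = padded.reshape(hh, f, ww, f, img.shape[2]).sum(axis=(1, 3), dtype=np.uint32)
    return np.rint(sums / (f * f)).astype(np.uint8)


def load_plane(path: str | Path, target_ds: int = 2, source_id: str = "") -> SlidePlane:
    """Read a level-0 PNG/TIFF/OME-TIFF and area-average down to ``target_ds``."""
    if target_ds not in VALID_DS:
        raise ValueError(f"unsupported downsample factor {target_ds}; expected one of {VALID_DS}")
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise OSError(f"cannot read slide image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = np.ascontiguousarray(arr[..., :3]).astype(np.uint8)
    return SlidePlane(_block_mean(arr, target_ds), ds_factor=target_ds, source_id=source_id or path.stem)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int], offset=(0, 0)) -> np.ndarray:
    """Pixel-center-inside rasterization (ties inside) of a polygon on a grid."""
    h, w = shape
    ox, oy = offset
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel() + ox + 0.5, yy.ravel() + oy + 0.5])
    mask = MplPath(vertices).contains_points(centers, radius=1e-9)
    return mask.reshape(h, w)


def extract_roll(plane: SlidePlane, annotation: PolygonAnnotation, roll_id: str = "") -> RollCanvas:
    """Crop a swiss roll along its polygon onto a white canvas.

    Canvas dimensions are the polygon bounding box rounded up to the next
    multiple of 4 (white right/bottom padding); pixels outside the polygon
    are whitened.
    """
    if plane.ds_factor != 2:
        raise ValueError("roll extraction operates on the DS2 plane")
    poly = annotation.shapely
    if poly.area == 0:
        raise ValueError("degenerate polygon (zero area)")
    h, w = plane.pixels.shape[:2]
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError("annotation extends outside the slide plane")
    x0, y0 = int(np.floor(minx)), int(np.floor(miny))
    bw, bh = int(np.ceil(maxx)) - x0, int(np.ceil(maxy)) - y0
    cw, ch = bw + (-bw) % 4, bh + (-bh) % 4
    canvas = np.full((ch, cw, 3), 255, dtype=np.uint8)
    src = plane.pixels[y0 : y0 + bh, x0 : x0 + bw]
    mask = rasterize_polygon(annotation.vertices, (bh, bw), offset=(x0, y0))
    region = canvas[:bh, :bw]
    region[mask] = src[mask]
    return RollCanvas(canvas, ds_factor=2, roll_id=roll_id, crop_offset=(x0, y0))


def downscale_canvas(canvas: RollCanvas, factor: int = 4) -> RollCanvas:
    """Exact DS2 -> DS8 area-average; dimensions must already divide by 4."""
    if canvas.ds_factor != 2:
        raise ValueError("downscale_canvas expects a DS2 canvas")
    h, w = canvas.shape
    if h % factor or w % factor:
        raise ValueError(f"canvas dimensions {w}x{h} are not divisible by {factor}")
    return RollCanvas(
        _block_mean(canvas.pixels, factor),
        ds_factor=canvas.ds_factor * factor,
        roll_id=canvas.roll_id,
        crop_offset=canvas.crop_offset,
    )


# ---------------------------------------------------------------------------
# Disk round-trip


def write_canvas(canvas: RollCanvas, path: str | Path) -> None:
    path = Path(path)
    Image.fromarray(canvas.pixels).save(path)
    sidecar = {
        "ds_factor": canvas.ds_factor,
        "roll_id": canvas.roll_id,
        "crop_offset": list(canvas.crop_offset),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_canvas(path: str | Path) -> RollCanvas:
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("RGB"))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RollCanvas(
        pixels,
        ds_factor=int(meta.get("ds_factor", 2)),
        roll_id=meta.get("roll_id", path.stem),
        crop_offset=tuple(meta.get("crop_offset", (0, 0))),
    )


def load_annotations(path: str | Path) -> list[PolygonAnnotation]:
    """Read roll outlines from GeoJSON (Polygon features with a roll_index
    property) or a plain JSON list of vertex lists."""
    data = json.loads(Path(path).read_text())
    anns = []
    if isinstance(data, dict) and data.get("type") == "FeatureCollection":
        for feat in data["features"]:
            verts = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
            idx = int(feat.get("properties", {}).get("roll_index", len(anns) + 1))
            anns.append(PolygonAnnotation(verts, roll_index=idx))
    else:
        for i, verts in enumerate(data, start=1):
            anns.append(PolygonAnnotation(np.asarray(verts, dtype=float), roll_index=i))
    return anns
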