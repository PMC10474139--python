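"""Fully ground-truthed synthetic IHC-H&E serial-section stacks and cohorts.

The generator emulates the data layout of a swiss-rolled murine colon study:
section 1 is an H&E-like image whose zones carry exactly decodable color
codes per tissue category and histology patch class; sections 2..n are
single-marker IHC-like images (pale hematoxylin background, brown DAB disks
at planted positions, near-black crystal-artifact specks), each rendered
through its cumulative inter-section rigid (optionally warped) transform.
Every planted quantity — transforms, blob centers/areas, artifact positions,
per-patch tissue-category fractions and class labels — is recorded in a
manifest in the reference frame of section 1.

Default cohort signatures plant the directional findings the pipeline is
meant to recover: CD8b enrichment in 'Crypt Dilation' zones of the
Klf5-like genetic-colitis condition, CD8b depletion in 'Crypt Dilation' and
'Crypt Dropout' zones of the DSS-like chemical-colitis condition, and a
CD8b excess in DSS-like 'Uninvolved' zones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .catalog import (
    ALL_CLASSES,
    ARTIFACT_COLOR,
    CATEGORY_COLORS,
    CLASS_COLORS,
    DAB_RGB,
    IHC_BACKGROUND,
    INVOLVED_CLASSES,
    MARKERS,
    TISSUE_CATEGORIES,
    UNINVOLVED_CLASSES,
)
from .slide_io import RollCanvas, rasterize_polygon
from .transforms import (
    AffineTransform2D,
    CompositeTransform,
    SinusoidalWarp,
    SpatialTransform,
    transform_from_dict,
)

CONDITIONS = ("Control", "Klf5-like", "DSS-like")

#: blobs per zone at multiplier 1.0
DEFAULT_BASE_DENSITY = 8.0

#: condition -> class (involved class name or "Uninvolved") -> marker -> multiplier.
#: Unlisted (class, marker) cells fall back to the condition's Uninvolved row.
DEFAULT_SIGNATURES: dict[str, dict[str, dict[str, float]]] = {
    "Control": {
        "Uninvolved": {"CD8b": 0.75, "CD3": 1.0, "CD4": 0.75},
    },
    "Klf5-like": {
        "Uninvolved": {"CD8b": 0.75, "CD3": 1.0, "CD4": 0.75},
        "Inflammatory": {"CD8b": 1.25, "CD3": 1.0, "CD4": 1.5},
        "Crypt Dilation": {"CD8b": 1.75, "CD3": 1.5, "CD4": 1.25},
    },
    "DSS-like": {
        "Uninvolved": {"CD8b": 1.5, "CD3": 1.0, "CD4": 0.75},
        "Crypt Dilation": {"CD8b": 0.5, "CD3": 1.5, "CD4": 1.5},
        "Crypt Dropout": {"CD8b": 0.5, "CD3": 1.5, "CD4": 1.5},
    },
}

#: class mixes over the 12 default class zones per roll
DEFAULT_CLASS_MIX: dict[str, dict[str, int]] = {
    "Control": {"Crypts": 4, "Lightly Packed": 3, "Rosettes": 3, "Inflammatory": 1, "Distorted Glands": 1},
    "Klf5-like": {"Crypts": 2, "Lightly Packed": 2, "Rosettes": 1, "Inflammatory": 3, "Crypt Dilation": 4},
    "DSS-like": {"Crypts": 2, "Lightly Packed": 2, "Rosettes": 1, "Crypt Dropout": 4, "Crypt Dilation": 3},
}


@dataclass
class Zone:
    polygon: np.ndarray  # (N, 2) DS2 reference-frame vertices
    category: str  # Tissue / Submucosa / Muscle / Background
    histo_class: str | None = None

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        if self.category not in TISSUE_CATEGORIES:
            raise ValueError(f"unknown tissue category {self.category!r}")
        if self.histo_class is not None and self.histo_class not in ALL_CLASSES:
            raise ValueError(f"unknown histology class {self.histo_class!r}")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


def rect_zone(x0, y0, x1, y1, category, histo_class=None) -> Zone:
    """Axis-aligned half-open rectangle [x0, x1) x [y0, y1)."""
    return Zone(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]), category, histo_class)


@dataclass
class SyntheticStackSpec:
    canvas_size: tuple[int, int]  # (width, height) at DS2
    zones: list[Zone]
    blob_counts: dict[str, list[int]]  # marker -> count per zone
    blob_radius_range: tuple[int, int] = (4, 9)
    artifact_counts: dict[str, list[int]] | None = None  # marker -> count per zone
    transforms: list[dict] = field(default_factory=list)  # per IHC section
    seed: int = 0
    densities: dict[str, list[float]] | None = None  # expected counts, bookkeeping

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.blob_counts.keys())

    def validate(self) -> None:
        w, h = self.canvas_size
        if w % 4 or h % 4:
            raise ValueError("canvas dimensions must be divisible by 4")
        canvas = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
        polys = [z.shapely for z in self.zones]
        for i, p in enumerate(polys):
            if not canvas.contains(p.buffer(-1e-9)):
                raise ValueError(f"zone {i} extends outside the canvas")
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersection(polys[j]).area > 1e-6:
                    raise ValueError(f"zones {i} and {j} overlap")
        for marker, counts in self.blob_counts.items():
            if len(counts) != len(self.zones):
                raise ValueError(f"blob counts for {marker} do not match zone count")
        rmin, rmax = self.blob_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("invalid blob radius range")
        n_sections = len(self.transforms)
        if n_sections != len(self.markers):
            raise ValueError("one inter-section transform per IHC section is required")


@dataclass
class GroundTruthManifest:
    canvas_size: tuple[int, int]
    transforms: list[SpatialTransform]  # per section (index 0 = H&E, identity)
    markers: tuple[str, ...]
    zones: list[dict]
    blobs: dict[str, list[dict]]  # marker -> [{zone, center, radius, area_px}]
    artifacts: dict[str, list[dict]]
    patches: list[dict]  # DS8 grid truths: x, y, category_fractions, histo_class
    densities: dict[str, list[float]] | None = None
    seed: int = 0

    def blob_centers(self, marker: str) -> np.ndarray:
        items = self.blobs[marker]
        return np.array([b["center"] for b in items], dtype=float).reshape(-1, 2)

    def window_blob_count(self, marker: str, x_ds2: float, y_ds2: float, size: int = 896) -> int:
        c = self.blob_centers(marker)
        if len(c) == 0:
            return 0
        inside = (c[:, 0] >= x_ds2) & (c[:, 0] < x_ds2 + size) & (c[:, 1] >= y_ds2) & (c[:, 1] < y_ds2 + size)
        return int(inside.sum())

    def patch_truth(self, x_ds8: int, y_ds8: int) -> dict | None:
        for p in self.patches:
            if p["x"] == x_ds8 and p["y"] == y_ds8:
                return p
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "canvas_size": list(self.canvas_size),
                "transforms": [t.to_dict() for t in self.transforms],
                "markers": list(self.markers),
                "zones": self.zones,
                "blobs": self.blobs,
                "artifacts": self.artifacts,
                "patches": self.patches,
                "densities": self.densities,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            canvas_size=tuple(d["canvas_size"]),
            transforms=[transform_from_dict(t) for t in d["transforms"]],
            markers=tuple(d["markers"]),
            zones=d["zones"],
            blobs=d["blobs"],
            artifacts=d["artifacts"],
            patches=d["patches"],
            densities=d.get("densities"),
            seed=d.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# rendering primitives


def _axis_rect_bounds(verts: np.ndarray) -> tuple[int, int, int, int] | None:
    """Integer bounds of an axis-aligned rectangle polygon, else None."""
    if len(verts) != 4:
        return None
    xs, ys = np.unique(verts[:, 0]), np.unique(verts[:, 1])
    if len(xs) != 2 or len(ys) != 2:
        return None
    if not (np.allclose(xs, np.rint(xs)) and np.allclose(ys, np.rint(ys))):
        return None
    return int(xs[0]), int(ys[0]), int(xs[1]), int(ys[1])


def _paint_zones(shape_hw: tuple[int, int], zones: list[Zone], scale: float = 1.0) -> np.ndarray:
    """Index map of zones (-1 = no zone) using pixel-center-inside rasterization.

    Integer axis-aligned rectangles (the common case) are painted by slicing,
    which is exactly the half-open pixel-center rule.
    """
    h, w = shape_hw
    idx = np.full((h, w), -1, dtype=np.int16)
    for i, zone in enumerate(zones):
        verts = zone.polygon / scale
        rect = _axis_rect_bounds(verts)
        if rect is not None:
            x0, y0, x1, y1 = rect
            idx[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)] = i
            continue
        x0 = max(int(np.floor(verts[:, 0].min())), 0)
        y0 = max(int(np.floor(verts[:, 1].min())), 0)
        x1 = min(int(np.ceil(verts[:, 0].max())), w)
        y1 = min(int(np.ceil(verts[:, 1].max())), h)
        if x1 <= x0 or y1 <= y0:
            continue
        mask = rasterize_polygon(verts, (y1 - y0, x1 - x0), offset=(x0, y0))
        sub = idx[y0:y1, x0:x1]
        sub[mask] = i
    return idx


def _draw_disk(img: np.ndarray, cx: float, cy: float, r: float, color) -> int:
    """Paint a disk (integer-coordinate center rule); returns pixel area."""
    h, w = img.shape[:2]
    x0, x1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, w)
    y0, y1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    img[y0:y1, x0:x1][mask] = color
    return int(mask.sum())


def _place_points(
    rng: np.random.Generator,
    zone: Zone,
    n: int,
    margin: float,
    min_sep: float,
    existing: list[tuple[float, float]],
    zone_index: int,
    max_tries_per_point: int = 300,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers inside the zone shrunk by ``margin``."""
    if n == 0:
        return []
    inner = zone.shapely.buffer(-margin)
    if inner.is_empty:
        raise ValueError(f"zone {zone_index} is too small for blob margin {margin}")
    minx, miny, maxx, maxy = inner.bounds
    placed: list[tuple[float, float]] = []
    all_pts = list(existing)
    for _ in range(n):
        for attempt in range(max_tries_per_point):
            x = float(np.round(rng.uniform(minx, maxx)))
            y = float(np.round(rng.uniform(miny, maxy)))
            if not inner.contains(Point(x, y)):
                continue
            if all(((x - px) ** 2 + (y - py) ** 2) >= min_sep**2 for px, py in all_pts):
                placed.append((x, y))
                all_pts.append((x, y))
                break
        else:
            raise ValueError(f"could not place {n} blobs in zone {zone_index} without overlap")
    return placed


def render_he_reference(spec: SyntheticStackSpec, zone_index_map: np.ndarray | None = None) -> np.ndarray:
    w, h = spec.canvas_size
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    idx = zone_index_map if zone_index_map is not None else _paint_zones((h, w), spec.zones)
    for i, zone in enumerate(spec.zones):
        if zone.category == "Background":
            continue
        if zone.category == "Tissue":
            if zone.histo_class is None:
                raise ValueError(f"Tissue zone {i} has no histology class")
            color = CLASS_COLORS[zone.histo_class]
        else:
            color = CATEGORY_COLORS[zone.category]
        img[idx == i] = color
    return img


def render_ihc_reference(
    spec: SyntheticStackSpec,
    blobs: list[dict],
    artifacts: list[dict],
    zone_index_map: np.ndarray | None = None,
) -> np.ndarray:
    w, h = spec.canvas_size
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    idx = zone_index_map if zone_index_map is not None else _paint_zones((h, w), spec.zones)
    img[idx >= 0] = IHC_BACKGROUND
    for b in blobs:
        b["area_px"] = _draw_disk(img, b["center"][0], b["center"][1], b["radius"], DAB_RGB)
    for a in artifacts:
        a["area_px"] = _draw_disk(img, a["center"][0], a["center"][1], a["radius"], ARTIFACT_COLOR)
    return img


def _warp_section(ref: np.ndarray, cum: SpatialTransform, zones: list[Zone]) -> np.ndarray:
    """Resample the reference-frame render into the section's own frame.

    out(x_section) = ref(cum(x_section)). Only the section-frame bounding box
    of the warped tissue region is resampled; everything else is white by
    construction.
    """
    h, w = ref.shape[:2]
    verts = np.vstack([z.polygon for z in zones])
    corners = np.array(
        [
            [verts[:, 0].min(), verts[:, 1].min()],
            [verts[:, 0].max(), verts[:, 1].min()],
            [verts[:, 0].max(), verts[:, 1].max()],
            [verts[:, 0].min(), verts[:, 1].max()],
        ]
    )
    sec_corners = cum.inverse().apply(corners)
    pad = 16
    x0 = int(max(np.floor(sec_corners[:, 0].min()) - pad, 0))
    y0 = int(max(np.floor(sec_corners[:, 1].min()) - pad, 0))
    x1 = int(min(np.ceil(sec_corners[:, 0].max()) + pad, w))
    y1 = int(min(np.ceil(sec_corners[:, 1].max()) + pad, h))
    out = np.full_like(ref, 255)
    if x1 > x0 and y1 > y0:
        sub = cum.inverse().warp_image(
            ref, output_shape=(y1 - y0, x1 - x0), order=0, cval=255, output_origin=(x0, y0)
        )
        out[y0:y1, x0:x1] = sub
    return out


def _step_transform(params: dict, center: tuple[float, float]) -> SpatialTransform:
    rigid = AffineTransform2D.rigid(
        params.get("rotation_deg", 0.0),
        tuple(params.get("translation", (0.0, 0.0))),
        center=center,
    )
    amp = params.get("warp_amplitude", 0.0)
    if amp:
        warp = SinusoidalWarp(amp, params.get("warp_period", 512.0))
        return CompositeTransform([rigid, warp])
    return rigid


def _patch_truths(spec: SyntheticStackSpec, patch_size: int = 224) -> list[dict]:
    w8, h8 = spec.canvas_size[0] // 4, spec.canvas_size[1] // 4
    cat_of_zone = np.array(
        [TISSUE_CATEGORIES.index(z.category) for z in spec.zones], dtype=np.int16
    )
    class_of_zone = np.array(
        [ALL_CLASSES.index(z.histo_class) if z.histo_class else -1 for z in spec.zones],
        dtype=np.int16,
    )
    idx8 = _paint_zones((h8, w8), spec.zones, scale=4.0)
    bg = TISSUE_CATEGORIES.index("Background")
    cat_map = np.where(idx8 >= 0, cat_of_zone[np.clip(idx8, 0, None)], bg)
    cls_map = np.where(idx8 >= 0, class_of_zone[np.clip(idx8, 0, None)], -1)
    out = []
    for y in range(0, h8 - patch_size + 1, patch_size):
        for x in range(0, w8 - patch_size + 1, patch_size):
            cat_tile = cat_map[y : y + patch_size, x : x + patch_size]
            cls_tile = cls_map[y : y + patch_size, x : x + patch_size]
            counts = np.bincount(cat_tile.ravel(), minlength=len(TISSUE_CATEGORIES))
            fracs = {c: float(counts[i]) / patch_size**2 for i, c in enumerate(TISSUE_CATEGORIES)}
            cls_counts = np.bincount(cls_tile[cls_tile >= 0].ravel(), minlength=len(ALL_CLASSES))
            label = ALL_CLASSES[int(cls_counts.argmax())] if cls_counts.sum() else None
            out.append({"x": int(x), "y": int(y), "category_fractions": fracs, "histo_class": label})
    return out


def generate_stack(spec: SyntheticStackSpec) -> tuple[list[RollCanvas], GroundTruthManifest]:
    """Render one synthetic stack: section 1 H&E-like, sections 2..n IHC-like.

    All ground truth is in the reference frame of section 1; IHC sections are
    resampled (nearest-neighbor, so the color codes stay exact) through the
    inverse of their cumulative transform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.canvas_size
    center = (w / 2.0, h / 2.0)
    rmin, rmax = spec.blob_radius_range
    margin = rmax + 8
    # two max-radius disks at separation exactly 2*rmax are tangent and share
    # rasterized pixels; +2 px guarantees disjoint (hence countable) rasters
    min_sep = 2.0 * rmax + 2

    transforms: list[SpatialTransform] = [AffineTransform2D.identity()]
    for params in spec.transforms:
        step = _step_transform(params, center)
        transforms.append(transforms[-1].compose(step))

    zone_idx = _paint_zones((h, w), spec.zones)
    he = render_he_reference(spec, zone_index_map=zone_idx)
    sections = [RollCanvas(he, ds_factor=2, roll_id="section01")]

    blobs: dict[str, list[dict]] = {}
    artifacts: dict[str, list[dict]] = {}
    for k, marker in enumerate(spec.markers):
        marker_blobs: list[dict] = []
        marker_artifacts: list[dict] = []
        for zi, zone in enumerate(spec.zones):
            n = int(spec.blob_counts[marker][zi])
            centers = _place_points(rng, zone, n, margin, min_sep, [], zi)
            for cx, cy in centers:
                r = int(rng.integers(rmin, rmax + 1))
                marker_blobs.append({"zone": zi, "center": (cx, cy), "radius": r})
            n_art = int(spec.artifact_counts[marker][zi]) if spec.artifact_counts else 0
            art_centers = _place_points(rng, zone, n_art, margin, min_sep, centers, zi)
            for cx, cy in art_centers:
                marker_artifacts.append({"zone": zi, "center": (cx, cy), "radius": 4})
        ref = render_ihc_reference(spec, marker_blobs, marker_artifacts, zone_index_map=zone_idx)
        cum = transforms[k + 1]
        section_img = _warp_section(ref, cum, spec.zones)
        sections.append(RollCanvas(section_img, ds_factor=2, roll_id=f"section{k + 2:02d}"))
        blobs[marker] = marker_blobs
        artifacts[marker] = marker_artifacts

    manifest = GroundTruthManifest(
        canvas_size=spec.canvas_size,
        transforms=transforms,
        markers=spec.markers,
        zones=[
            {"polygon": z.polygon.tolist(), "category": z.category, "histo_class": z.histo_class}
            for z in spec.zones
        ],
        blobs=blobs,
        artifacts=artifacts,
        patches=_patch_truths(spec),
        densities=spec.densities,
        seed=spec.seed,
    )
    return sections, manifest


# ---------------------------------------------------------------------------
# default roll layout


def default_layout(
    n_class_rows: int = 3,
    n_class_cols: int = 4,
    zone_px: int = 896,
    margin_px: int = 896,
    submucosa_px: int = 224,
    muscle_px: int = 672,
) -> tuple[tuple[int, int], list[Zone]]:
    """Rectangular roll layout at DS2: a grid of class zones over a submucosa
    strip and muscle band, inside a white margin ring.

    With the defaults every class zone covers exactly one 224-px DS8 analysis
    patch and all strips align to the patch grid, so planted patch labels are
    unambiguous.
    """
    width = 2 * margin_px + n_class_cols * zone_px
    height = 2 * margin_px + n_class_rows * zone_px + submucosa_px + muscle_px
    zones: list[Zone] = []
    for r in range(n_class_rows):
        for c in range(n_class_cols):
            x0 = margin_px + c * zone_px
            y0 = margin_px + r * zone_px
            zones.append(rect_zone(x0, y0, x0 + zone_px, y0 + zone_px, "Tissue"))
    y_sub = margin_px + n_class_rows * zone_px
    zones.append(rect_zone(margin_px, y_sub, width - margin_px, y_sub + submucosa_px, "Submucosa"))
    y_mus = y_sub + submucosa_px
    zones.append(rect_zone(margin_px, y_mus, width - margin_px, y_mus + muscle_px, "Muscle"))
    return (width, height), zones


def _mix_to_assignment(mix: dict[str, int], n_zones: int, rng: np.random.Generator) -> list[str]:
    total = sum(mix.values())
    base = {k: v * n_zones // total for k, v in mix.items()}
    rem = n_zones - sum(base.values())
    order = sorted(mix, key=lambda k: -(mix[k] * n_zones % total))
    for k in order[:rem]:
        base[k] += 1
    labels = [k for k, v in base.items() for _ in range(v)]
    return [labels[i] for i in rng.permutation(n_zones)]


def signature_multiplier(table: dict, condition: str, histo_class: str | None, marker: str) -> float:
    cond = table[condition]
    uninv = cond.get("Uninvolved", {})
    key = histo_class if histo_class in INVOLVED_CLASSES else "Uninvolved"
    row = cond.get(key, uninv)
    return float(row.get(marker, uninv.get(marker, 1.0)))


@dataclass
class SyntheticMouse:
    mouse_id: str
    condition: str
    sections: list[RollCanvas]
    manifest: GroundTruthManifest


def generate_cohort(
    n_per_condition: dict[str, int] | None = None,
    signature_table: dict | None = None,
    seed: int = 0,
    base_density: float = DEFAULT_BASE_DENSITY,
    layout_kwargs: dict | None = None,
    max_step_rotation: float = 4.0,
    max_step_translation: float = 20.0,
) -> tuple[list[SyntheticMouse], pd.DataFrame]:
    """One synthetic stack per mouse with condition-specific planted signatures."""
    n_per_condition = n_per_condition or {"Control": 2, "Klf5-like": 2, "DSS-like": 2}
    table = signature_table or DEFAULT_SIGNATURES
    for cond in n_per_condition:
        if cond not in DEFAULT_CLASS_MIX or cond not in table:
            raise ValueError(f"unknown condition {cond!r}")
        if n_per_condition[cond] < 1:
            raise ValueError("need at least one mouse per condition")
    canvas_size, zone_template = default_layout(**(layout_kwargs or {}))
    class_zone_idx = [i for i, z in enumerate(zone_template) if z.category == "Tissue"]

    mice: list[SyntheticMouse] = []
    rows = []
    i_mouse = 0
    for cond in n_per_condition:
        abbr = cond[0]
        for j in range(n_per_condition[cond]):
            child_seed = int(np.random.SeedSequence([seed, i_mouse]).generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child_seed)
            zones = [Zone(z.polygon.copy(), z.category, z.histo_class) for z in zone_template]
            mix = dict(DEFAULT_CLASS_MIX[cond])
            if j % 2 == 1:
                # inter-mouse variability: every second mouse carries one more
                # zone of its condition's dominant involved class, taken from
                # the dominant uninvolved class (severity varies across mice)
                src = max(UNINVOLVED_CLASSES, key=lambda c: mix.get(c, 0))
                dst = max(INVOLVED_CLASSES, key=lambda c: mix.get(c, 0))
                if mix.get(src, 0) > 1:
                    mix[src] -= 1
                    mix[dst] = mix.get(dst, 0) + 1
            assignment = _mix_to_assignment(mix, len(class_zone_idx), rng)
            for zi, label in zip(class_zone_idx, assignment):
                zones[zi] = Zone(zones[zi].polygon, "Tissue", label)
            blob_counts: dict[str, list[int]] = {}
            densities: dict[str, list[float]] = {}
            artifact_counts: dict[str, list[int]] = {}
            for marker in MARKERS:
                lam, counts, arts = [], [], []
                for z in zones:
                    if z.category == "Tissue":
                        mult = signature_multiplier(table, cond, z.histo_class, marker)
                        lam_z = base_density * mult
                        counts.append(min(int(rng.poisson(lam_z)), 30))
                        arts.append(1)
                    else:
                        lam_z = 0.0
                        counts.append(0)
                        arts.append(0)
                    lam.append(lam_z)
                blob_counts[marker] = counts
                densities[marker] = lam
                artifact_counts[marker] = arts
            steps = [
                {
                    "rotation_deg": float(rng.uniform(-max_step_rotation, max_step_rotation)),
                    "translation": (
                        float(rng.uniform(-max_step_translation, max_step_translation)),
                        float(rng.uniform(-max_step_translation, max_step_translation)),
                    ),
                }
                for _ in MARKERS
            ]
            spec = SyntheticStackSpec(
                canvas_size=canvas_size,
                zones=zones,
                blob_counts=blob_counts,
                artifact_counts=artifact_counts,
                transforms=steps,
                seed=child_seed,
                densities=densities,
            )
            sections, manifest = generate_stack(spec)
            mouse_id = f"{abbr}{j + 1}"
            for s in sections:
                s.roll_id = f"{mouse_id}_r1"
            mice.append(SyntheticMouse(mouse_id, cond, sections, manifest))
            rows.append({"mouse_id": mouse_id, "condition": cond, "n_sections": len(sections)})
            i_mouse += 1
    return mice, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standalone IHC patches (for detector calibration tests)


def generate_ihc_patch(
    n_blobs: int,
    n_artifacts: int = 0,
    size: int = 448,
    seed: int = 0,
    radius_range: tuple[int, int] = (4, 9),
    fuse_artifact_to_blob: int | None = None,
) -> tuple[np.ndarray, list[dict], list[dict]]:
    """A single IHC-like patch with planted, well-separated DAB disks.

    ``fuse_artifact_to_blob`` plants one extra artifact speck overlapping the
    given blob index (for exclusion tests).
    """
    rng = np.random.default_rng(seed)
    rmin, rmax = radius_range
    zone = rect_zone(0, 0, size, size, "Tissue", "Crypts")
    img = np.full((size, size, 3), IHC_BACKGROUND, dtype=np.uint8)
    centers = _place_points(rng, zone, n_blobs, rmax + 6, 2.0 * rmax + 2, [], 0)
    blobs = []
    for cx, cy in centers:
        r = int(rng.integers(rmin, rmax + 1))
        area = _draw_disk(img, cx, cy, r, DAB_RGB)
        blobs.append({"center": (cx, cy), "radius": r, "area_px": area})
    art_centers = _place_points(rng, zone, n_artifacts, rmax + 6, 2.0 * rmax, centers, 0)
    artifacts = []
    for cx, cy in art_centers:
        area = _draw_disk(img, cx, cy, 4, ARTIFACT_COLOR)
        artifacts.append({"center": (cx, cy), "radius": 4, "area_px": area})
    if fuse_artifact_to_blob is not None:
        bx, by = blobs[fuse_artifact_to_blob]["center"]
        r = blobs[fuse_artifact_to_blob]["radius"]
        area = _draw_disk(img, bx + r, by, 4, ARTIFACT_COLOR)
        artifacts.append({"center": (bx + r, by), "radius": 4, "area_px": area, "fused": True})
    return img, blobs, artifacts


# ---------------------------------------------------------------------------
# disk layout for the CLI


def write_stack(mouse: SyntheticMouse, out_dir: str | Path) -> None:
    from .slide_io import write_canvas

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sec in enumerate(mouse.sections, start=1):
        write_canvas(sec, out / f"section_{i:02d}.png")
    (out / "manifest.json").write_text(mouse.manifest.to_json())
    (out / "mouse.json").write_text(json.dumps({"mouse_id": mouse.mouse_id, "condition": mouse.condition}))


def load_stack(stack_dir: str | Path) -> SyntheticMouse:
    from .slide_io import read_canvas

    d = Path(stack_dir)
    meta = json.loads((d / "mouse.json").read_text())
    manifest = GroundTruthManifest.from_json((d / "manifest.json").read_text())
    sections = [read_canvas(p) for p in sorted(d.glob("section_*.png"))]
    return SyntheticMouse(meta["mouse_id"], meta["condition"], sections, manifest)
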