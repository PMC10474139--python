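"""Joining IHC counts to H&E patch labels, Uninvolved normalization, the 10%
class-frequency weighting, pseudo-multiplex overlays and the comparison
statistics.

H&E patch outputs live at DS8 and IHC detections at DS2; the join multiplies
H&E coordinates by 4. Involved-patch counts are normalized within each mouse
by that mouse's mean count over Uninvolved patches for the same marker, so a
normalized value above 1.0 marks enrichment relative to the mouse's own
healthy-looking regions. Involved classes below 10% frequency of a
condition's involved patches get weight 0 and are dropped from the
cross-condition statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import INVOLVED_CLASSES, MARKER_PALETTE, MARKERS
from .ihc import DetectionResult
from .slide_io import RollCanvas

FREQUENCY_CUTOFF = 0.10
ENRICHMENT_CUTOFF = 1.0


def join_ihc_to_he(
    detections: dict[str, list[DetectionResult]],
    patches: pd.DataFrame,
    mouse_id: str,
    condition: str,
) -> pd.DataFrame:
    """Inner-join detections (DS2) to labeled kept grid patches (DS8) by the
    x4 coordinate law; one row per (patch, marker)."""
    keyed = {(int(r["x"]), int(r["y"])): r for _, r in patches.iterrows()}
    rows = []
    seen: dict[str, set[tuple[int, int]]] = {m: set() for m in detections}
    for marker, dets in detections.items():
        for det in dets:
            key = (det.x_ds2 // 4, det.y_ds2 // 4)
            if det.x_ds2 % 4 or det.y_ds2 % 4 or key not in keyed:
                raise ValueError(
                    f"orphan detection at DS2 ({det.x_ds2}, {det.y_ds2}) for {marker}: "
                    "no kept H&E patch maps there via x4"
                )
            seen[marker].add(key)
            rec = keyed[key]
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "condition": condition,
                    "x": key[0],
                    "y": key[1],
                    "label": rec["label"],
                    "involved_class": rec.get("involved_class"),
                    "marker": marker,
                    "object_count": det.object_count,
                    "artifact_count": det.artifact_count,
                    "excluded_by_aggregate": det.excluded_by_aggregate,
                }
            )
    for marker, s in seen.items():
        missing = set(keyed) - s
        if missing:
            raise ValueError(f"kept patches without {marker} detections: {sorted(missing)[:5]}")
    return pd.DataFrame(rows)


def render_pseudo_multiplex(
    he: RollCanvas,
    masks_per_marker: dict[str, np.ndarray],
    palette: dict[str, tuple[int, int, int]] | None = None,
    alpha: float = 1.0,
) -> np.ndarray:
    """Tint retained-positivity pixels per marker on the DS2 H&E base.

    Markers are drawn in catalog order; overlapping markers show the
    last-drawn color.
    """
    palette = palette if palette is not None else MARKER_PALETTE
    out = he.pixels.astype(float).copy()
    for marker in MARKERS:
        if marker not in masks_per_marker:
            continue
        if marker not in palette:
            raise ValueError(f"palette has no color for marker {marker}")
        m = masks_per_marker[marker].astype(bool)
        color = np.array(palette[marker], dtype=float)
        out[m] = (1 - alpha) * out[m] + alpha * color
    extra = set(masks_per_marker) - set(MARKERS)
    for marker in sorted(extra):
        if marker not in palette:
            raise ValueError(f"palette has no color for marker {marker}")
        m = masks_per_marker[marker].astype(bool)
        out[m] = (1 - alpha) * out[m] + alpha * np.array(palette[marker], dtype=float)
    return out.astype(np.uint8)


def _statistical(stacked: pd.DataFrame) -> pd.DataFrame:
    return stacked[~stacked["excluded_by_aggregate"]]


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sample t-test with the degenerate zero-variance limits made exact
    (identical groups -> t=0, p=1; separated constant groups -> |t|=inf)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    return float(t), float(p)


def mean_uninvolved(stacked: pd.DataFrame, mouse_id: str, marker: str) -> tuple[float, bool]:
    """Mean count over a mouse's non-excluded Uninvolved patches for a marker.

    Returns (mean, mean_is_zero flag); raises when no such patches exist.
    """
    rows = _statistical(stacked)
    sel = rows[(rows["mouse_id"] == mouse_id) & (rows["marker"] == marker) & (rows["label"] == "Uninvolved")]
    if len(sel) == 0:
        raise ValueError(f"mouse {mouse_id} has no Uninvolved patches for {marker}")
    m = float(sel["object_count"].mean())
    return m, m == 0.0


def uninvolved_means(stacked: pd.DataFrame) -> pd.DataFrame:
    rows = []
    stat = _statistical(stacked)
    for (mouse, marker), _ in stat.groupby(["mouse_id", "marker"]):
        m, zero = mean_uninvolved(stacked, mouse, marker)
        rows.append({"mouse_id": mouse, "marker": marker, "uninvolved_mean": m, "mean_is_zero": zero})
    return pd.DataFrame(rows)


def normalize_involved(
    stacked: pd.DataFrame, means: pd.DataFrame | None = None, log: list | None = None
) -> pd.DataFrame:
    """Divide involved-patch counts by the mouse-marker Uninvolved mean.

    Rows whose Uninvolved mean is zero are undefined and dropped from the
    statistics (with a logged count).
    """
    means = means if means is not None else uninvolved_means(stacked)
    stat = _statistical(stacked)
    inv = stat[stat["label"] == "Involved"].merge(means, on=["mouse_id", "marker"], how="left")
    undefined = inv["mean_is_zero"] | inv["uninvolved_mean"].isna()
    n_drop = int(undefined.sum())
    if n_drop and log is not None:
        log.append(f"dropped {n_drop} involved rows with undefined (zero-mean) normalization")
    inv = inv[~undefined].copy()
    inv["normalized_count"] = inv["object_count"] / inv["uninvolved_mean"]
    return inv


def frequency_weights(stacked: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, involved class): weight 1 iff the class reaches at
    least 10% of that condition's involved patches across the dataset.

    Frequencies are computed over unique patches (not per-marker rows).
    """
    stat = _statistical(stacked)
    inv = stat[stat["label"] == "Involved"].drop_duplicates(subset=["mouse_id", "x", "y"])
    rows = []
    for cond, grp in inv.groupby("condition"):
        total = len(grp)
        if total == 0:
            continue
        for cls in INVOLVED_CLASSES:
            freq = float((grp["involved_class"] == cls).sum()) / total
            rows.append(
                {"condition": cond, "involved_class": cls, "frequency": freq,
                 "weight": 1 if freq >= FREQUENCY_CUTOFF else 0}
            )
    return pd.DataFrame(rows)


def compare_inv_vs_uninv(
    stacked: pd.DataFrame, marker: str, condition: str, equal_var: bool = False
) -> dict:
    """Two-sample t-test of counts, Uninvolved vs Involved, within a condition."""
    stat = _statistical(stacked)
    sel = stat[(stat["marker"] == marker) & (stat["condition"] == condition)]
    uninv = sel[sel["label"] == "Uninvolved"]["object_count"].to_numpy(float)
    inv = sel[sel["label"] == "Involved"]["object_count"].to_numpy(float)
    if len(uninv) < 2 or len(inv) < 2:
        raise ValueError("each group needs at least 2 patches")
    t, p = _ttest(uninv, inv, equal_var)
    return {
        "marker": marker,
        "condition": condition,
        "t": float(t),
        "p": float(p),
        "mean_uninvolved": float(uninv.mean()),
        "mean_involved": float(inv.mean()),
        "n_uninvolved": len(uninv),
        "n_involved": len(inv),
    }


def compare_across_conditions(
    normalized: pd.DataFrame,
    stacked: pd.DataFrame,
    weights: pd.DataFrame,
    equal_var: bool = False,
    log: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-condition statistics.

    Returns (anova, uninvolved_pairwise, enrichment):
      * one-way ANOVA of normalized counts across conditions per
        (involved class, marker), restricted to weight-1 (condition, class)
        cells;
      * pairwise t-tests of raw Uninvolved counts between conditions per
        marker;
      * enrichment calls: mean normalized count > 1.0 per weight-1
        (condition, class, marker).
    """
    wmap = {(r["condition"], r["involved_class"]): r["weight"] for _, r in weights.iterrows()}
    anova_rows, enrich_rows = [], []
    for (cls, marker), grp in normalized.groupby(["involved_class", "marker"]):
        groups, conds = [], []
        for cond, sub in grp.groupby("condition"):
            if wmap.get((cond, cls), 0) != 1:
                continue
            vals = sub["normalized_count"].to_numpy(float)
            if len(vals) >= 2:
                groups.append(vals)
                conds.append(cond)
            mean_norm = float(vals.mean()) if len(vals) else np.nan
            enrich_rows.append(
                {
                    "condition": cond,
                    "involved_class": cls,
                    "marker": marker,
                    "mean_normalized": mean_norm,
                    "enriched": bool(mean_norm > ENRICHMENT_CUTOFF),
                    "n": len(vals),
                }
            )
        if len(groups) >= 2:
            f, p = stats.f_oneway(*groups)
            anova_rows.append(
                {"involved_class": cls, "marker": marker, "conditions": ",".join(conds),
                 "F": float(f), "p": float(p)}
            )
        elif log is not None:
            log.append(f"ANOVA skipped for ({cls}, {marker}): fewer than 2 eligible conditions")
    stat = _statistical(stacked)
    uninv = stat[stat["label"] == "Uninvolved"]
    pair_rows = []
    for marker, grp in uninv.groupby("marker"):
        conds = sorted(grp["condition"].unique())
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = grp[grp["condition"] == conds[i]]["object_count"].to_numpy(float)
                b = grp[grp["condition"] == conds[j]]["object_count"].to_numpy(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                t, p = _ttest(a, b, equal_var)
                pair_rows.append(
                    {"marker": marker, "condition_a": conds[i], "condition_b": conds[j],
                     "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "t": float(t), "p": float(p)}
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(pair_rows), pd.DataFrame(enrich_rows)
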