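"""Involved/Uninvolved confidence averaging, k-means patch classes, per-roll
class proportions and the LDA condition check.

The disease classifier scores every overlapping patch; its involved
confidence is averaged at every covered pixel, which de-noises the
prediction against the particular tiling that happened to be extracted.
Grid patches are labeled from the averaged field (>= 0.5 -> Involved; the
tie goes to Involved, favoring sensitivity). Involved and Uninvolved patches
are embedded, reduced by PCA and clustered with k-means into the named
phenotype classes; per-roll class proportions feed a linear discriminant
analysis that predicts the mouse condition as an internal control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestCentroid

from .catalog import CLASS_COLORS, INVOLVED_CLASSES, UNINVOLVED_CLASSES
from .contracts import PatchClassifier
from .slide_io import RollCanvas
from .tissue_map import PatchRecord, TissueMap

INVOLVED_THRESHOLD = 0.5


@dataclass
class ConfidenceField:
    """Per-pixel running sum of involved confidence and coverage count."""

    total: np.ndarray  # float64 (H, W)
    count: np.ndarray  # int64 (H, W)

    @property
    def mean(self) -> np.ndarray:
        """Mean involved confidence where covered; NaN elsewhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.total / self.count, np.nan)


def accumulate_confidence(
    canvas: RollCanvas,
    patches: list[PatchRecord],
    classifier: PatchClassifier,
) -> tuple[ConfidenceField, dict[tuple[int, int], float]]:
    """Score every kept patch and spread its confidence over its footprint.

    Returns the field plus the raw per-patch involved confidence (keyed by
    patch top-left), which the embedding step reuses.
    """
    h, w = canvas.shape
    total = np.zeros((h, w))
    count = np.zeros((h, w), dtype=np.int64)
    raw: dict[tuple[int, int], float] = {}
    for rec in patches:
        p_inv, _ = classifier.predict(canvas.pixels[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size])
        raw[(rec.x, rec.y)] = p_inv
        total[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size] += p_inv
        count[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size] += 1
    return ConfidenceField(total, count), raw


def render_binary_overlay(field: ConfidenceField, tmap: TissueMap, he: RollCanvas) -> np.ndarray:
    """Red tint where mean involved confidence >= 0.5, green where below;
    Muscle/Background cells and uncovered pixels are left untinted."""
    if field.total.shape != he.shape:
        raise ValueError("field and canvas dimensions differ")
    mean = field.mean
    out = he.pixels.astype(float).copy()
    covered = field.count > 0
    eligible = covered & ~tmap.noninformative_pixels
    red = eligible & (mean >= INVOLVED_THRESHOLD)
    green = eligible & (mean < INVOLVED_THRESHOLD)
    out[red] = 0.5 * out[red] + 0.5 * np.array([255.0, 0.0, 0.0])
    out[green] = 0.5 * out[green] + 0.5 * np.array([0.0, 255.0, 0.0])
    return out.astype(np.uint8)


def label_patch(record: PatchRecord, field: ConfidenceField) -> str:
    """Involved iff the averaged field over the patch footprint is >= 0.5."""
    win_t = field.total[record.y : record.y + record.size, record.x : record.x + record.size]
    win_c = field.count[record.y : record.y + record.size, record.x : record.x + record.size]
    if (win_c == 0).any():
        raise ValueError(f"patch at ({record.x}, {record.y}) has uncovered pixels")
    mean = float((win_t / win_c).mean())
    return "Involved" if mean >= INVOLVED_THRESHOLD else "Uninvolved"


@dataclass
class ClassModels:
    """Fitted PCA + k-means with cluster -> class-name assignment."""

    pca: PCA
    kmeans: KMeans
    names: list[str]  # per cluster index

    def to_dict(self) -> dict:
        return {
            "pca_mean": self.pca.mean_.tolist(),
            "pca_components": self.pca.components_.tolist(),
            "centroids": self.kmeans.cluster_centers_.tolist(),
            "names": self.names,
        }


def fit_class_models(
    embeddings: np.ndarray,
    k: int,
    n_components: int = 32,
    seed: int = 0,
    true_labels: list[str] | None = None,
) -> ClassModels:
    """PCA (default 32 components) then seeded k-means on the projections.

    On synthetic data ``true_labels`` names each cluster by its majority
    ground-truth class; otherwise clusters keep numeric names.
    """
    emb = np.asarray(embeddings, dtype=float)
    if emb.ndim != 2:
        raise ValueError("embeddings must be a 2-D array")
    if k > len(emb):
        raise ValueError(f"cannot fit {k} classes from {len(emb)} embeddings")
    n_comp = min(n_components, emb.shape[0], emb.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed).fit(emb)
    proj = pca.transform(emb)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(proj)
    if true_labels is not None:
        names = []
        labels = np.asarray(true_labels)
        for c in range(k):
            members = labels[km.labels_ == c]
            names.append(pd.Series(members).mode().iloc[0] if len(members) else str(c))
    else:
        names = [str(c) for c in range(k)]
    return ClassModels(pca, km, names)


def assign_class(embedding: np.ndarray, models: ClassModels) -> str:
    """Nearest-centroid class in PCA space; ties break to the lowest index."""
    emb = np.asarray(embedding, dtype=float).reshape(1, -1)
    if emb.shape[1] != models.pca.mean_.shape[0]:
        raise ValueError(f"embedding length {emb.shape[1]} does not match the fitted model")
    proj = models.pca.transform(emb)
    d = ((models.kmeans.cluster_centers_ - proj) ** 2).sum(axis=1)
    return models.names[int(np.argmin(d))]


PROPORTION_COLUMNS = ["Uninvolved", *INVOLVED_CLASSES]


def compute_proportions(records: pd.DataFrame) -> pd.Series:
    """Per-roll proportions over kept grid patches: pooled Uninvolved plus
    each involved class. ``records`` needs columns label + involved_class."""
    if len(records) == 0:
        raise ValueError("no kept grid patches to compute proportions from")
    n = len(records)
    out = {"Uninvolved": float((records["label"] == "Uninvolved").sum()) / n}
    inv = records[records["label"] == "Involved"]
    for cls in INVOLVED_CLASSES:
        out[cls] = float((inv["involved_class"] == cls).sum()) / n
    return pd.Series(out, index=PROPORTION_COLUMNS)


def lda_check(
    proportions: pd.DataFrame,
    labels: pd.Series | list[str],
    mode: str = "fit-predict",
    model: LinearDiscriminantAnalysis | None = None,
) -> tuple[np.ndarray, LinearDiscriminantAnalysis]:
    """LDA on per-roll proportion vectors; the internal condition control.

    When the within-class scatter is exactly singular (e.g. one roll per
    condition) the discriminant degenerates to its nearest-class-centroid
    limit, which is fitted instead.
    """
    X = np.asarray(proportions, dtype=float)
    y = np.asarray(labels)
    if mode in ("fit", "fit-predict"):
        if len(np.unique(y)) < 2:
            raise ValueError("LDA requires at least two conditions")
        if np.allclose(X.var(axis=0), 0):
            raise ValueError(
                "degenerate scatter: all proportion vectors identical; consider shrinkage regularization"
            )
        try:
            model = LinearDiscriminantAnalysis().fit(X, y)
        except (IndexError, np.linalg.LinAlgError):
            model = NearestCentroid().fit(X, y)
    if model is None:
        raise ValueError("predict mode requires a fitted model")
    return model.predict(X), model
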