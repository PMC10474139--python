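"""End-to-end orchestration: registration -> H&E characterization -> IHC
detection -> immune-context mapping, for one mouse or a whole cohort.

The cohort entry point is ``analyze_cohort``: it registers every stack,
builds tissue maps and confidence fields at DS8, labels and embeds the kept
grid patches, fits the cohort-level PCA + k-means phenotype classes, detects
DAB positivity in the H&E-guided DS2 windows of each registered IHC section,
joins everything into a stacked count table and produces the normalized
counts, frequency weights and comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import INVOLVED_CLASSES, MARKERS, UNINVOLVED_CLASSES
from .contracts import ColorCodePatchClassifier, ColorCodeSmallPatchClassifier
from .histology import (
    ClassModels,
    ConfidenceField,
    accumulate_confidence,
    assign_class,
    compute_proportions,
    fit_class_models,
    label_patch,
    lda_check,
)
from .ihc import DetectionResult, MarkerConfig, detect_roll
from .immunomap import (
    compare_across_conditions,
    compare_inv_vs_uninv,
    frequency_weights,
    join_ihc_to_he,
    normalize_involved,
    render_pseudo_multiplex,
    uninvolved_means,
)
from .registration import DEFAULT_QC_THRESHOLD, RegistrationQC, register_stack
from .slide_io import RollCanvas, downscale_canvas
from .synth import SyntheticMouse
from .tissue_map import PatchRecord, all_analysis_patches, build_tissue_map, grid_patches
from .transforms import SpatialTransform


@dataclass
class AnalysisConfig:
    marker_configs: dict[str, MarkerConfig] = field(
        default_factory=lambda: {m: MarkerConfig(m) for m in MARKERS}
    )
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    pca_components: int = 32
    model_seed: int = 0
    grid2d: bool = False
    equal_var: bool = False
    aggregate_masks: dict[str, list] = field(default_factory=dict)  # mouse_id -> polygons (DS2)

    def validate(self, markers=MARKERS) -> None:
        for m in markers:
            if m not in self.marker_configs:
                raise ValueError(f"missing MarkerConfig for marker {m}")


@dataclass
class MouseAnalysis:
    """Per-mouse results. Registered IHC composites are not retained (they
    are full-canvas rasters); rebuild them from ``transforms`` when needed."""

    mouse_id: str
    condition: str
    transforms: list[SpatialTransform]
    qc: list[RegistrationQC]
    he_ds8: RollCanvas
    tissue_map: object
    field: ConfidenceField
    patches: pd.DataFrame  # kept grid patches with labels/embeddings index
    embeddings: dict[tuple[int, int], np.ndarray]
    detections: dict[str, list[DetectionResult]]


def _registered_windows(
    transform: SpatialTransform,
    section: RollCanvas,
    ref_shape: tuple[int, int],
    coords_ds8: list[tuple[int, int]],
    win: int = 4 * 224,
) -> RollCanvas:
    """White composite holding the registered section only at the DS2 windows."""
    composite = np.full((*ref_shape, 3), 255, dtype=np.uint8)
    for x8, y8 in coords_ds8:
        x, y = 4 * x8, 4 * y8
        composite[y : y + win, x : x + win] = transform.warp_image(
            section.pixels, output_shape=(win, win), order=0, cval=255, output_origin=(x, y)
        )
    return RollCanvas(composite, ds_factor=2, roll_id=section.roll_id)


def analyze_mouse(mouse: SyntheticMouse, config: AnalysisConfig) -> MouseAnalysis:
    """Register one stack, characterize its H&E and count IHC positivity."""
    markers = tuple(mouse.manifest.markers)
    config.validate(markers)
    sections = mouse.sections
    chain = register_stack(sections, qc_threshold=config.qc_threshold)
    he = sections[0]
    he_ds8 = downscale_canvas(he)
    small_clf = ColorCodeSmallPatchClassifier()
    patch_clf = ColorCodePatchClassifier()
    tmap = build_tissue_map(he_ds8, small_clf)
    analysis = all_analysis_patches(he_ds8, tmap, grid2d=config.grid2d)
    conf_field, _ = accumulate_confidence(he_ds8, analysis, patch_clf)

    kept_grid = [p for p in grid_patches(he_ds8, tmap) if p.keep]
    rows, embeddings = [], {}
    for rec in kept_grid:
        label = label_patch(rec, conf_field)
        pix = he_ds8.pixels[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size]
        embeddings[(rec.x, rec.y)] = patch_clf.embed(pix)
        win_t = conf_field.total[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size]
        win_c = conf_field.count[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size]
        truth = mouse.manifest.patch_truth(rec.x, rec.y) or {}
        rows.append(
            {
                "mouse_id": mouse.mouse_id,
                "condition": mouse.condition,
                "x": rec.x,
                "y": rec.y,
                "non_informative_fraction": rec.non_informative_fraction,
                "p_involved_mean": float((win_t / win_c).mean()),
                "label": label,
                "involved_class": None,
                "uninvolved_class": None,
                "true_class": truth.get("histo_class"),
            }
        )
    patches = pd.DataFrame(rows)

    # Resample each IHC section into the reference frame. Only the H&E-guided
    # DS2 windows are consumed downstream, so only those are rendered; the
    # composite is discarded after counting.
    coords = [(int(r["x"]), int(r["y"])) for _, r in patches.iterrows()]
    detections = {}
    for k, marker in enumerate(markers, start=1):
        t, _ = chain[k]
        composite = _registered_windows(t, sections[k], he.shape, coords)
        detections[marker] = detect_roll(
            composite,
            coords,
            config.marker_configs[marker],
            aggregate_masks=config.aggregate_masks.get(mouse.mouse_id),
        )
    return MouseAnalysis(
        mouse_id=mouse.mouse_id,
        condition=mouse.condition,
        transforms=[t for t, _ in chain],
        qc=[q for _, q in chain],
        he_ds8=he_ds8,
        tissue_map=tmap,
        field=conf_field,
        patches=patches,
        embeddings=embeddings,
        detections=detections,
    )


@dataclass
class CohortResult:
    analyses: list[MouseAnalysis]
    involved_models: ClassModels | None
    uninvolved_models: ClassModels | None
    patches: pd.DataFrame
    proportions: pd.DataFrame
    lda_predictions: pd.DataFrame
    stacked: pd.DataFrame
    means: pd.DataFrame
    normalized: pd.DataFrame
    weights: pd.DataFrame
    inv_vs_uninv: pd.DataFrame
    anova: pd.DataFrame
    uninvolved_pairwise: pd.DataFrame
    enrichment: pd.DataFrame
    log: list[str]

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patches": self.patches,
            "proportions": self.proportions,
            "lda_predictions": self.lda_predictions,
            "stacked_counts": self.stacked,
            "uninvolved_means": self.means,
            "normalized_counts": self.normalized,
            "class_weights": self.weights,
            "stats_inv_vs_uninv": self.inv_vs_uninv,
            "stats_anova": self.anova,
            "stats_uninvolved_pairwise": self.uninvolved_pairwise,
            "enrichment": self.enrichment,
        }


def _fit_and_assign(analyses: list[MouseAnalysis], config: AnalysisConfig) -> tuple[ClassModels | None, ClassModels | None]:
    """Cohort-level PCA + k-means for involved (k=4) and uninvolved (k=3)."""

    def collect(label):
        embs, truths, keys = [], [], []
        for a in analyses:
            for _, r in a.patches[a.patches["label"] == label].iterrows():
                key = (int(r["x"]), int(r["y"]))
                embs.append(a.embeddings[key])
                truths.append(r["true_class"])
                keys.append((a.mouse_id, key))
        return np.array(embs), truths, keys

    inv_emb, inv_truth, inv_keys = collect("Involved")
    uninv_emb, uninv_truth, uninv_keys = collect("Uninvolved")
    inv_models = uninv_models = None
    have_truth = all(t is not None for t in inv_truth)
    if len(inv_emb) >= len(INVOLVED_CLASSES):
        inv_models = fit_class_models(
            inv_emb, k=len(INVOLVED_CLASSES), n_components=config.pca_components,
            seed=config.model_seed, true_labels=inv_truth if have_truth else None,
        )
    if len(uninv_emb) >= len(UNINVOLVED_CLASSES):
        uninv_models = fit_class_models(
            uninv_emb, k=len(UNINVOLVED_CLASSES), n_components=config.pca_components,
            seed=config.model_seed,
            true_labels=uninv_truth if all(t is not None for t in uninv_truth) else None,
        )
    by_mouse = {a.mouse_id: a for a in analyses}
    if inv_models is not None:
        for mouse_id, key in inv_keys:
            a = by_mouse[mouse_id]
            sel = (a.patches["x"] == key[0]) & (a.patches["y"] == key[1])
            a.patches.loc[sel, "involved_class"] = assign_class(a.embeddings[key], inv_models)
    if uninv_models is not None:
        for mouse_id, key in uninv_keys:
            a = by_mouse[mouse_id]
            sel = (a.patches["x"] == key[0]) & (a.patches["y"] == key[1])
            a.patches.loc[sel, "uninvolved_class"] = assign_class(a.embeddings[key], uninv_models)
    return inv_models, uninv_models


def analyze_cohort(
    mice: list[SyntheticMouse],
    config: AnalysisConfig | None = None,
    release_sections: bool = False,
) -> CohortResult:
    """Analyze every stack and assemble the cohort tables.

    ``release_sections=True`` frees each mouse's section rasters once that
    mouse is analyzed — the statistics need only the derived tables, and a
    full-size cohort holds gigabytes of raster otherwise.
    """
    config = config or AnalysisConfig()
    log: list[str] = []
    analyses = []
    for m in mice:
        analyses.append(analyze_mouse(m, config))
        if release_sections:
            m.sections = []
    inv_models, uninv_models = _fit_and_assign(analyses, config)

    patches = pd.concat([a.patches for a in analyses], ignore_index=True)
    prop_rows = []
    for a in analyses:
        vec = compute_proportions(a.patches)
        prop_rows.append({"mouse_id": a.mouse_id, "condition": a.condition, **vec.to_dict()})
    proportions = pd.DataFrame(prop_rows)

    feats = proportions.drop(columns=["mouse_id", "condition"])
    lda_predictions = proportions[["mouse_id", "condition"]].copy()
    try:
        preds, _ = lda_check(feats, proportions["condition"])
        lda_predictions["predicted"] = preds
    except ValueError as exc:
        log.append(f"LDA control skipped: {exc}")
        lda_predictions["predicted"] = None

    stacked = pd.concat(
        [join_ihc_to_he(a.detections, a.patches, a.mouse_id, a.condition) for a in analyses],
        ignore_index=True,
    )
    means = uninvolved_means(stacked)
    normalized = normalize_involved(stacked, means, log=log)
    weights = frequency_weights(stacked)

    ivu_rows = []
    for cond in stacked["condition"].unique():
        for marker in stacked["marker"].unique():
            try:
                ivu_rows.append(compare_inv_vs_uninv(stacked, marker, cond, equal_var=config.equal_var))
            except ValueError as exc:
                log.append(f"inv-vs-uninv skipped for ({cond}, {marker}): {exc}")
    inv_vs_uninv = pd.DataFrame(ivu_rows)

    anova, pairwise, enrichment = compare_across_conditions(
        normalized, stacked, weights, equal_var=config.equal_var, log=log
    )
    return CohortResult(
        analyses=analyses,
        involved_models=inv_models,
        uninvolved_models=uninv_models,
        patches=patches,
        proportions=proportions,
        lda_predictions=lda_predictions,
        stacked=stacked,
        means=means,
        normalized=normalized,
        weights=weights,
        inv_vs_uninv=inv_vs_uninv,
        anova=anova,
        uninvolved_pairwise=pairwise,
        enrichment=enrichment,
        log=log,
    )


def pseudo_multiplex_for_mouse(
    analysis: MouseAnalysis, mouse: SyntheticMouse, config: AnalysisConfig
) -> np.ndarray:
    """Re-detect with masks kept and composite the marker overlay at DS2.

    Registered canvases are rebuilt from the stored chain transforms, so the
    analysis object itself stays light.
    """
    he = mouse.sections[0]
    h, w = he.shape
    masks = {}
    coords = [(int(r["x"]), int(r["y"])) for _, r in analysis.patches.iterrows()]
    for k, marker in enumerate(mouse.manifest.markers, start=1):
        canvas = _registered_windows(analysis.transforms[k], mouse.sections[k], he.shape, coords)
        full = np.zeros((h, w), dtype=bool)
        dets = detect_roll(
            canvas, coords, config.marker_configs[marker],
            aggregate_masks=config.aggregate_masks.get(analysis.mouse_id), keep_masks=True,
        )
        for det in dets:
            if det.positive_mask is None:
                continue
            ph, pw = det.positive_mask.shape
            full[det.y_ds2 : det.y_ds2 + ph, det.x_ds2 : det.x_ds2 + pw] |= det.positive_mask.astype(bool)
        masks[marker] = full
    return render_pseudo_multiplex(he, masks)
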