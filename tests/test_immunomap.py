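"""Cross-resolution join, Uninvolved normalization, frequency weights,
pseudo-multiplex rendering and comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from ihcmap.ihc import DetectionResult
from ihcmap.immunomap import (
    compare_across_conditions,
    compare_inv_vs_uninv,
    frequency_weights,
    join_ihc_to_he,
    mean_uninvolved,
    normalize_involved,
    render_pseudo_multiplex,
    uninvolved_means,
)
from ihcmap.slide_io import RollCanvas

MARKERS = ("CD8b", "CD3", "CD4")


def make_patches(n=10, n_involved=4):
    rows = []
    for i in range(n):
        involved = i < n_involved
        rows.append(
            {
                "x": 224 * i,
                "y": 0,
                "label": "Involved" if involved else "Uninvolved",
                "involved_class": "Inflammatory" if involved else None,
            }
        )
    return pd.DataFrame(rows)


def make_detections(patches, counts=None, excluded=frozenset()):
    dets = {}
    for m in MARKERS:
        dets[m] = [
            DetectionResult(
                4 * int(r["x"]), 4 * int(r["y"]), m,
                int(counts[i]) if counts is not None else i,
                [], 0, excluded_by_aggregate=(i in excluded),
            )
            for i, r in patches.iterrows()
        ]
    return dets


class TestJoin:
    def test_cardinality(self):
        patches = make_patches()
        stacked = join_ihc_to_he(make_detections(patches), patches, "m1", "Control")
        assert len(stacked) == 30

    def test_excluded_rows_flagged(self):
        patches = make_patches()
        stacked = join_ihc_to_he(make_detections(patches, excluded={0, 1}), patches, "m1", "Control")
        assert stacked["excluded_by_aggregate"].sum() == 6
        assert len(stacked[~stacked["excluded_by_aggregate"]]) == 24

    def test_orphan_detection_rejected(self):
        patches = make_patches()
        dets = make_detections(patches)
        dets["CD8b"][0].x_ds2 += 4  # no longer maps to a kept patch
        with pytest.raises(ValueError, match="orphan"):
            join_ihc_to_he(dets, patches, "m1", "Control")


class TestPseudoMultiplex:
    def _he(self):
        return RollCanvas(np.full((64, 64, 3), 220, dtype=np.uint8), ds_factor=2)

    def test_empty_masks_identity(self):
        out = render_pseudo_multiplex(self._he(), {m: np.zeros((64, 64), bool) for m in MARKERS})
        assert np.array_equal(out, self._he().pixels)

    def test_single_blob_exact_pixels(self):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        out = render_pseudo_multiplex(self._he(), {"CD8b": mask})
        changed = (out != 220).any(axis=2)
        assert np.array_equal(changed, mask)

    def test_disjoint_markers_area_bookkeeping(self):
        m1 = np.zeros((64, 64), bool); m1[5:10, 5:10] = True
        m2 = np.zeros((64, 64), bool); m2[30:40, 30:40] = True
        out = render_pseudo_multiplex(self._he(), {"CD8b": m1, "CD3": m2})
        assert (out != 220).any(axis=2).sum() == m1.sum() + m2.sum()

    def test_missing_palette_color_rejected(self):
        with pytest.raises(ValueError, match="palette"):
            render_pseudo_multiplex(self._he(), {"CD8b": np.zeros((64, 64), bool)}, palette={})


def make_stacked(counts_by_label, mouse_id="m1", condition="Control", marker="CD8b"):
    rows = []
    for label, counts in counts_by_label.items():
        for i, c in enumerate(counts):
            rows.append(
                {
                    "mouse_id": mouse_id, "condition": condition, "x": i, "y": 0,
                    "label": label, "involved_class": "Inflammatory" if label == "Involved" else None,
                    "marker": marker, "object_count": c, "artifact_count": 0,
                    "excluded_by_aggregate": False,
                }
            )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_mean_uninvolved(self):
        stacked = make_stacked({"Uninvolved": [2, 4, 6]})
        assert mean_uninvolved(stacked, "m1", "CD8b") == (4.0, False)

    def test_single_patch_mean(self):
        stacked = make_stacked({"Uninvolved": [7]})
        assert mean_uninvolved(stacked, "m1", "CD8b") == (7.0, False)

    def test_zero_mean_flagged(self):
        stacked = make_stacked({"Uninvolved": [0, 0, 0]})
        assert mean_uninvolved(stacked, "m1", "CD8b") == (0.0, True)

    def test_no_uninvolved_rejected(self):
        stacked = make_stacked({"Involved": [1, 2]})
        with pytest.raises(ValueError, match="no Uninvolved"):
            mean_uninvolved(stacked, "m1", "CD8b")

    def test_normalized_values(self):
        stacked = make_stacked({"Uninvolved": [2, 4, 6], "Involved": [6, 0]})
        norm = normalize_involved(stacked)
        assert sorted(norm["normalized_count"]) == [0.0, 1.5]

    def test_zero_mean_rows_dropped_with_log(self):
        stacked = make_stacked({"Uninvolved": [0, 0], "Involved": [3, 5]})
        log = []
        norm = normalize_involved(stacked, log=log)
        assert len(norm) == 0
        assert any("undefined" in line for line in log)

    def test_uninvolved_self_normalization_is_one(self):
        rng = np.random.default_rng(0)
        stacked = make_stacked({"Uninvolved": list(rng.poisson(8, 40) + 1)})
        means = uninvolved_means(stacked)
        m = means["uninvolved_mean"].iloc[0]
        normalized = stacked["object_count"] / m
        assert normalized.mean() == pytest.approx(1.0, abs=1e-9)


class TestFrequencyWeights:
    def _stacked_with_classes(self, class_counts, condition="DSS-like"):
        rows = []
        i = 0
        for cls, n in class_counts.items():
            for _ in range(n):
                rows.append(
                    {
                        "mouse_id": "m1", "condition": condition, "x": i, "y": 0,
                        "label": "Involved", "involved_class": cls, "marker": "CD8b",
                        "object_count": 1, "artifact_count": 0, "excluded_by_aggregate": False,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_threshold_pattern(self):
        stacked = self._stacked_with_classes(
            {"Inflammatory": 50, "Crypt Dropout": 35, "Crypt Dilation": 9, "Distorted Glands": 6}
        )
        w = frequency_weights(stacked).set_index("involved_class")["weight"]
        assert w["Inflammatory"] == 1 and w["Crypt Dropout"] == 1
        assert w["Crypt Dilation"] == 0 and w["Distorted Glands"] == 0

    def test_exactly_ten_percent_is_weight_one(self):
        stacked = self._stacked_with_classes({"Inflammatory": 9, "Crypt Dilation": 1})
        w = frequency_weights(stacked).set_index("involved_class")["weight"]
        assert w["Crypt Dilation"] == 1

    def test_single_class_condition(self):
        w = frequency_weights(self._stacked_with_classes({"Inflammatory": 5}))
        w = w.set_index("involved_class")["weight"]
        assert w["Inflammatory"] == 1 and w.drop("Inflammatory").sum() == 0

    def test_weight_idempotence(self):
        stacked = self._stacked_with_classes(
            {"Inflammatory": 50, "Crypt Dropout": 35, "Crypt Dilation": 9, "Distorted Glands": 6}
        )
        w1 = frequency_weights(stacked)
        keep = {(r["condition"], r["involved_class"]) for _, r in w1.iterrows() if r["weight"] == 1}
        reduced = stacked[
            stacked.apply(lambda r: (r["condition"], r["involved_class"]) in keep, axis=1)
        ]
        w2 = frequency_weights(reduced).set_index("involved_class")["weight"]
        for cls in ("Inflammatory", "Crypt Dropout"):
            assert w2[cls] == 1


class TestComparisons:
    def test_identical_groups_null_t(self):
        stacked = make_stacked({"Uninvolved": [3, 3, 3], "Involved": [3, 3, 3]})
        res = compare_inv_vs_uninv(stacked, "CD8b", "Control")
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_planted_separation_significant(self):
        rng = np.random.default_rng(1)
        stacked = make_stacked(
            {"Uninvolved": list(0.01 * rng.random(8)), "Involved": list(5 + 0.01 * rng.random(8))}
        )
        assert compare_inv_vs_uninv(stacked, "CD8b", "Control")["p"] < 0.001

    def test_small_group_rejected(self):
        stacked = make_stacked({"Uninvolved": [1], "Involved": [2, 3]})
        with pytest.raises(ValueError, match="at least 2"):
            compare_inv_vs_uninv(stacked, "CD8b", "Control")

    def test_enrichment_threshold(self):
        rows = []
        for cond, val in (("Control", 0.99), ("DSS-like", 1.01)):
            for i in range(3):
                rows.append(
                    {
                        "mouse_id": f"{cond}-m", "condition": cond, "x": i, "y": 0,
                        "label": "Involved", "involved_class": "Inflammatory", "marker": "CD8b",
                        "object_count": 1, "artifact_count": 0, "excluded_by_aggregate": False,
                        "uninvolved_mean": 1.0, "mean_is_zero": False, "normalized_count": val,
                    }
                )
        normalized = pd.DataFrame(rows)
        weights = pd.DataFrame(
            [
                {"condition": c, "involved_class": "Inflammatory", "frequency": 1.0, "weight": 1}
                for c in ("Control", "DSS-like")
            ]
        )
        stacked = make_stacked({"Uninvolved": [1, 2, 3]})
        _, _, enrichment = compare_across_conditions(normalized, stacked, weights)
        by_cond = enrichment.set_index("condition")["enriched"]
        assert not by_cond["Control"]
        assert by_cond["DSS-like"]

    def test_null_anova_p_roughly_uniform(self):
        """Same-distribution conditions should not trigger the cross-condition
        ANOVA more often than chance."""
        rng = np.random.default_rng(2)
        conds = ("Control", "Klf5-like", "DSS-like")
        weights = pd.DataFrame(
            [{"condition": c, "involved_class": "Inflammatory", "frequency": 1.0, "weight": 1} for c in conds]
        )
        stacked = make_stacked({"Uninvolved": [1, 2, 3]})
        ps = []
        for _ in range(100):
            rows = []
            for c in conds:
                for i, v in enumerate(rng.normal(1.0, 0.3, 8)):
                    rows.append(
                        {
                            "mouse_id": f"{c}-m", "condition": c, "x": i, "y": 0,
                            "label": "Involved", "involved_class": "Inflammatory", "marker": "CD8b",
                            "object_count": 1, "artifact_count": 0, "excluded_by_aggregate": False,
                            "uninvolved_mean": 1.0, "mean_is_zero": False, "normalized_count": v,
                        }
                    )
            anova, _, _ = compare_across_conditions(pd.DataFrame(rows), stacked, weights)
            ps.append(anova["p"].iloc[0])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac < 0.15
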