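"""Evaluation metrics vs independent brute-force computations."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mtseg.metrics import (
    ConfusionCounts,
    case_metrics,
    confusion_counts,
    dice_score,
    hausdorff95,
    metrics_table,
    postprocess_enhancing_tumor,
    region_binarize,
    sensitivity_specificity,
)


def brute_force_hd95(gt, pred, spacing=(1.0, 1.0, 1.0), q=95.0):
    """Exhaustive all-pairs directed-distance percentile computation."""
    a = np.argwhere(gt) * np.asarray(spacing)
    b = np.argwhere(pred) * np.asarray(spacing)
    d = cdist(a, b)
    return max(np.percentile(d.min(axis=1), q), np.percentile(d.min(axis=0), q))


class TestRegions:
    def test_all_zero_labels(self):
        lab = np.zeros((3, 3, 3), dtype=int)
        for region in ("ET", "WT", "TC"):
            assert not region_binarize(lab, region).any()

    def test_one_voxel_per_label_set_arithmetic(self):
        lab = np.zeros((3, 3, 3), dtype=int)
        lab[0, 0, 0], lab[1, 1, 1], lab[2, 2, 2] = 1, 2, 4
        assert region_binarize(lab, "ET").sum() == 1
        assert region_binarize(lab, "TC").sum() == 2
        assert region_binarize(lab, "WT").sum() == 3

    def test_nesting_for_random_labels(self):
        lab = np.random.default_rng(0).choice([0, 1, 2, 4], size=(6, 6, 6))
        et, tc, wt = (region_binarize(lab, r) for r in ("ET", "TC", "WT"))
        assert (et <= tc).all() and (tc <= wt).all()

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            region_binarize(np.zeros((2, 2, 2), int), "NE")


class TestConfusion:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2] = True
        c = confusion_counts(m, m)
        assert (c.tp, c.tn, c.fp, c.fn) == (32, 32, 0, 0)

    def test_enumerated_two_by_two(self):
        gt = np.array([1, 1, 0, 0], bool)
        pred = np.array([1, 0, 1, 0], bool)
        c = confusion_counts(gt, pred)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)
        sens, spec = sensitivity_specificity(c)
        assert sens == 0.5 and spec == 0.5

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        gt, pred = rng.random((2, 5, 5, 5)) < 0.5
        c = confusion_counts(gt, pred)
        assert c.total == 125

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 3)))


class TestDice:
    def test_both_empty_scores_one(self):
        assert dice_score(ConfusionCounts(0, 0, 0, 8)) == 1.0

    def test_false_positive_on_empty_gt_scores_zero(self):
        assert dice_score(ConfusionCounts(0, 1, 0, 7)) == 0.0

    def test_hand_value(self):
        assert dice_score(ConfusionCounts(tp=2, fp=1, fn=1, tn=4)) == pytest.approx(4 / 6)

    def test_agrees_with_direct_formula_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gt, pred = rng.random((2, 6, 6, 6)) < rng.uniform(0.1, 0.9)
            c = confusion_counts(gt, pred)
            inter = np.count_nonzero(gt & pred)
            expected = 2 * inter / (gt.sum() + pred.sum()) if gt.any() or pred.any() else 1.0
            assert dice_score(c) == pytest.approx(expected)


class TestSensitivitySpecificity:
    def test_perfect_prediction(self):
        m = np.zeros((3, 3, 3), bool)
        m[1] = True
        sens, spec = sensitivity_specificity(confusion_counts(m, m))
        assert sens == 1.0 and spec == 1.0

    def test_all_positive_prediction_saturates(self):
        gt = np.zeros((3, 3, 3), bool)
        gt[0] = True
        pred = np.ones((3, 3, 3), bool)
        sens, spec = sensitivity_specificity(confusion_counts(gt, pred))
        assert sens == 1.0 and spec == 0.0

    def test_undefined_reported_as_nan(self):
        empty = np.zeros((2, 2, 2), bool)
        sens, _ = sensitivity_specificity(confusion_counts(empty, empty))
        assert math.isnan(sens)


class TestHausdorff95:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = m[2, 2, 3] = True
        assert hausdorff95(m, m) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((7, 7, 7), bool)
        b = np.zeros((7, 7, 7), bool)
        a[1, 3, 3] = True
        b[4, 3, 3] = True
        assert hausdorff95(a, b) == pytest.approx(3.0)

    def test_empty_mask_undefined(self):
        m = np.zeros((3, 3, 3), bool)
        full = ~m
        assert math.isnan(hausdorff95(m, full))
        assert math.isnan(hausdorff95(full, m))

    def test_spacing_scales_distances(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[1, 0, 0] = True
        assert hausdorff95(a, b, spacing=(2.5, 1, 1)) == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gt, pred = rng.random((2, 8, 8, 8)) < 0.2
        if not (gt.any() and pred.any()):
            pytest.skip("empty draw")
        assert hausdorff95(gt, pred) == pytest.approx(brute_force_hd95(gt, pred), abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        gt, pred = rng.random((2, 6, 6, 6)) < 0.3
        assert hausdorff95(gt, pred) == hausdorff95(pred, gt)


class TestPostprocessing:
    def make_pred(self, n_et):
        lab = np.zeros((20, 20, 20), dtype=int)
        flat = lab.reshape(-1)
        flat[:n_et] = 4
        flat[n_et : n_et + 50] = 1
        flat[n_et + 50 : n_et + 150] = 2
        return flat.reshape(20, 20, 20)

    def test_sub_threshold_et_relabeled_to_core(self):
        pred = self.make_pred(499)
        out = postprocess_enhancing_tumor(pred)
        assert (out == 4).sum() == 0
        assert (out == 1).sum() == 50 + 499

    def test_exactly_threshold_unchanged(self):
        pred = self.make_pred(500)
        assert np.array_equal(postprocess_enhancing_tumor(pred), pred)

    def test_no_et_unchanged(self):
        pred = self.make_pred(0)
        assert np.array_equal(postprocess_enhancing_tumor(pred), pred)

    def test_wt_and_tc_invariant(self):
        rng = np.random.default_rng(4)
        pred = rng.choice([0, 1, 2, 4], size=(12, 12, 12), p=[0.7, 0.1, 0.1, 0.1])
        out = postprocess_enhancing_tumor(pred, threshold=10**6)
        for region in ("WT", "TC"):
            assert np.array_equal(region_binarize(pred, region), region_binarize(out, region))
        assert (out == 4).sum() <= (pred == 4).sum()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            postprocess_enhancing_tumor(np.zeros((2, 2, 2), int), threshold=-1)


def test_case_metrics_perfect_prediction(small_case):
    _, labels = small_case
    result = case_metrics(labels, labels)
    for region in ("ET", "WT", "TC"):
        assert result[region]["dice"] == 1.0
        assert result[region]["sensitivity"] == 1.0
        assert result[region]["hausdorff95"] == 0.0


def test_metrics_table_has_summary_rows(small_case):
    _, labels = small_case
    table = metrics_table({"case0": case_metrics(labels, labels)})
    assert set(table[table.case_id == "__mean__"]["region"]) == {"ET", "WT", "TC"}
    assert (table[table.case_id == "__mean__"]["dice"] == 1.0).all()
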