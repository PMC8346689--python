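"""Evaluation metrics against hand-computed and brute-force oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priorseg.grid import LabelMap
from priorseg.metrics import (
    EXTERNAL_SCHEME,
    dice,
    evaluate_cohort,
    harmonize_external_labels,
    hd95,
    intra_lesion_accuracy,
    volume_similarity,
    z_compare,
)


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((4, 4, 4), dtype=int)
        a[1:3, 1:3, 1:3] = 2
        assert dice(a, a, 2) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), dtype=int)
        b = np.zeros((4, 4, 1), dtype=int)
        a[0, 0, 0] = 1
        b[3, 3, 0] = 1
        assert dice(a, b, 1) == 0.0

    def test_counted_example(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 4/6
        pred = np.array([[[1, 1], [1, 0]]])
        truth = np.array([[[1, 1], [0, 1]]])
        assert dice(pred, truth, 1) == pytest.approx(4 / 6)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), dtype=int)
        assert dice(z, z, 5) == 1.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), int), np.zeros((3, 3, 3), int), 1)


class TestVolumeSimilarity:
    def test_equal_volumes_even_if_disjoint(self):
        a = np.zeros((4, 4, 1), dtype=int)
        b = np.zeros((4, 4, 1), dtype=int)
        a[0, 0, 0] = 1
        b[3, 3, 0] = 1
        assert volume_similarity(a, b, 1) == 1.0

    def test_three_to_one(self):
        a = np.zeros((4, 4, 1), dtype=int)
        b = np.zeros((4, 4, 1), dtype=int)
        a[0, :3, 0] = 1
        b[0, 0, 0] = 1
        assert volume_similarity(a, b, 1) == pytest.approx(0.5)

    def test_one_empty(self):
        a = np.zeros((3, 3, 3), dtype=int)
        b = np.zeros((3, 3, 3), dtype=int)
        a[0, 0, 0] = 1
        assert volume_similarity(a, b, 1) == 0.0

    def test_permutation_invariance(self, rng):
        a = (rng.random((5, 5, 5)) < 0.3).astype(int)
        b = (rng.random((5, 5, 5)) < 0.3).astype(int)
        perm = rng.permutation(125)
        ap = a.ravel()[perm].reshape(5, 5, 5)
        bp = b.ravel()[perm].reshape(5, 5, 5)
        assert volume_similarity(a, b, 1) == volume_similarity(ap, bp, 1)


def _hd95_oracle(pred_mask, truth_mask, spacing):
    """Brute-force directed 95th percentile over all pairwise distances."""
    p = np.argwhere(pred_mask) * np.asarray(spacing)
    t = np.argwhere(truth_mask) * np.asarray(spacing)
    d = np.sqrt(((p[:, None, :] - t[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return float(np.percentile(d, 95, method="linear"))


class TestHD95:
    def test_identical_masks_zero(self):
        a = np.zeros((4, 4, 4), dtype=int)
        a[1:3, 1:3, 1:3] = 1
        assert hd95(a, a, 1) == 0.0

    def test_single_voxel_axis_distance(self):
        pred = np.zeros((8, 1, 1), dtype=int)
        truth = np.zeros((8, 1, 1), dtype=int)
        pred[0, 0, 0] = 1
        truth[3, 0, 0] = 1
        assert hd95(pred, truth, 1, spacing=(1, 1, 1)) == pytest.approx(3.0)

    def test_outlier_percentile_vs_oracle(self):
        pred = np.zeros((30, 1, 1), dtype=int)
        truth = np.zeros((30, 1, 1), dtype=int)
        pred[:19, 0, 0] = 1  # 19 at distance 0
        pred[29, 0, 0] = 1   # 1 at distance 10
        truth[:20, 0, 0] = 1  # truth covers 0..19
        got = hd95(pred, truth, 1)
        want = _hd95_oracle(pred == 1, truth == 1, (1, 1, 1))
        assert got == pytest.approx(want)

    def test_anisotropic_spacing(self):
        pred = np.zeros((4, 4, 4), dtype=int)
        truth = np.zeros((4, 4, 4), dtype=int)
        pred[0, 0, 2] = 1
        truth[0, 0, 0] = 1
        assert hd95(pred, truth, 1, spacing=(1, 1, 2.5)) == pytest.approx(5.0)

    def test_empty_mask_raises(self):
        a = np.zeros((3, 3, 3), dtype=int)
        b = np.zeros((3, 3, 3), dtype=int)
        b[0, 0, 0] = 1
        with pytest.raises(ValueError, match="empty"):
            hd95(a, b, 1)


class TestIntraLesionAccuracy:
    def test_perfect_wm(self):
        pred = np.full((3, 3, 3), 3, dtype=int)
        wm = np.zeros((3, 3, 3), bool)
        wm[0] = True
        acc_gm, acc_wm = intra_lesion_accuracy(pred, None, wm)
        assert acc_wm == 1.0 and acc_gm is None

    def test_gm_counts_cortical_and_deep(self):
        pred = np.zeros((4, 1, 1), dtype=int)
        pred[:, 0, 0] = [2, 4, 3, 0]
        gm = np.ones((4, 1, 1), bool)
        acc_gm, _ = intra_lesion_accuracy(pred, gm, None)
        assert acc_gm == pytest.approx(0.5)

    def test_all_background_prediction(self):
        pred = np.zeros((3, 3, 3), dtype=int)
        m = np.ones((3, 3, 3), bool)
        acc_gm, acc_wm = intra_lesion_accuracy(pred, m, m)
        assert acc_gm == 0.0 and acc_wm == 0.0


class TestZCompare:
    def test_identical_samples(self):
        z = z_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z.z == 0.0 and not z.significant

    def test_closed_form_table_style(self):
        # means 0.86/0.82, SDs 0.05/0.06, n=52 -> Z ~ 3.69 (significant)
        def sample(mean, sd, n=52):
            a = sd * math.sqrt((n - 1) / n)
            return [mean + a, mean - a] * (n // 2)
        z = z_compare(sample(0.86, 0.05), sample(0.82, 0.06))
        expect = 0.04 / math.sqrt((0.05**2 + 0.06**2) / 52)
        assert z.z == pytest.approx(expect, abs=1e-12)
        assert z.significant and z.direction == "model1_higher"

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 15)
        assert z_compare(a, b).z == pytest.approx(-z_compare(b, a).z, abs=1e-12)

    def test_zero_variance_cases(self):
        assert z_compare([1.0, 1.0], [1.0, 1.0]).z == 0.0
        z = z_compare([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(z.z) and z.z > 0


class TestEvaluateCohort:
    def test_single_subject_mean_equals_value(self, template64):
        _, lab = template64
        rep = evaluate_cohort([lab], [lab])
        assert rep["summary"]["overall_dice_mean"] == 1.0
        assert rep["summary"]["overall_dice_sd"] == 0.0
        for t in rep["summary"]["per_tissue"].values():
            assert t["dice_mean"] == 1.0
            assert t["hd95_mean_mm"] == 0.0

    def test_report_covers_every_class_once(self, template64):
        _, lab = template64
        rep = evaluate_cohort([lab], [lab])
        per = rep["per_subject"]
        assert sorted(per["class"].tolist()) == [1, 2, 3, 4, 5, 6]

    def test_subject_mismatch_raises(self, template64):
        _, lab = template64
        with pytest.raises(ValueError):
            evaluate_cohort([lab], [lab, lab])


class TestHarmonize:
    def _ext(self, data):
        return LabelMap(np.asarray(data, dtype=np.int16), np.eye(4),
                        dict(EXTERNAL_SCHEME))

    def test_ventricles_and_csf_condense(self):
        lab = self._ext(np.array([[[1, 6, 1, 6]]]))
        out, excl = harmonize_external_labels(lab)
        assert np.all(out.data == 1)
        assert not excl.any()

    def test_wmh_becomes_white_matter(self):
        out, _ = harmonize_external_labels(self._ext(np.array([[[4, 3]]])))
        assert np.all(out.data == 3)

    def test_infarction_excluded_from_metrics(self):
        ext = self._ext(np.array([[[9, 3, 10]]]))
        out, excl = harmonize_external_labels(ext)
        assert excl.tolist() == [[[True, False, True]]]
        # excluded voxels never enter the confusion counts
        pred = np.full_like(out.data, 3)
        assert dice(pred, out, 3, ignore=excl) == 1.0

    def test_unknown_code_raises(self):
        lab = LabelMap(np.array([[[11]]], dtype=np.int16), np.eye(4), {11: "x"})
        with pytest.raises(ValueError, match="unknown"):
            harmonize_external_labels(lab)

    def test_full_mapping(self):
        src = np.arange(11).reshape(1, 1, 11).astype(np.int16)
        out, excl = harmonize_external_labels(self._ext(src))
        assert out.data.ravel().tolist() == [0, 1, 4, 3, 3, 2, 1, 6, 5, 0, 0]
        assert excl.ravel().tolist() == [False] * 9 + [True, True]


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_metric_suite_invariant_under_relabeling(seed):
    """Dice/VS/HD95 are unchanged by a consistent permutation of codes."""
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, 4, (6, 6, 6))
    truth = rng.integers(0, 4, (6, 6, 6))
    perm = {0: 0, 1: 3, 2: 1, 3: 2}
    pred_p = np.vectorize(perm.get)(pred)
    truth_p = np.vectorize(perm.get)(truth)
    for c in (1, 2, 3):
        assert dice(pred, truth, c) == dice(pred_p, truth_p, perm[c])
        assert volume_similarity(pred, truth, c) == volume_similarity(pred_p, truth_p, perm[c])
        if (pred == c).any() and (truth == c).any():
            assert hd95(pred, truth, c) == hd95(pred_p, truth_p, perm[c])
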