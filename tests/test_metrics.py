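"""Confusion-matrix statistics: conventions, identities and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervicad.labels import OTHERS
from cervicad.metrics import (ConfusionMatrix, balanced_accuracy, detection_balanced_accuracy,
                              exclude_class, qwk_statistic, qwk_weight_matrix,
                              segmentation_metrics, weighted_prf)

count_matrices = st.lists(
    st.lists(st.integers(0, 50), min_size=3, max_size=3), min_size=3, max_size=3
).map(np.array).filter(lambda m: m.sum() > 0 and (m.sum(axis=0) > 0).all())


def brute_force_qwk(counts: np.ndarray) -> float:
    """Independent double-loop weighted kappa on an actual-by-predicted
    count matrix (transposed from the package's predicted-by-actual)."""
    x = counts.T.astype(float)
    n = x.shape[0]
    total = x.sum()
    num = den = 0.0
    for y in range(n):
        for yh in range(n):
            w = (y - yh) ** 2 / (n - 1) ** 2
            m = x[y].sum() * x[:, yh].sum() / total
            num += w * x[y, yh]
            den += w * m
    return 1.0 - num / den if den else 0.0


class TestBalancedAccuracy:
    def test_identity_matrix_is_perfect(self):
        assert balanced_accuracy(np.eye(3, dtype=int) * 5) == 1.0

    def test_macro_recall_definition(self):
        cm = np.array([[8, 2], [2, 8]])
        assert balanced_accuracy(cm) == pytest.approx(0.8)

    def test_empty_actual_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([[3, 0], [1, 0]]))


class TestWeightedPRF:
    def test_identity(self):
        assert weighted_prf(np.eye(4, dtype=int) * 3) == (1.0, 1.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(count_matrices)
    def test_weighted_sensitivity_is_micro_accuracy(self, counts):
        """Support-weighted recall is algebraically trace/total."""
        _, sens, _ = weighted_prf(counts)
        assert sens == pytest.approx(np.trace(counts) / counts.sum(), abs=1e-12)


class TestQWK:
    def test_diagonal_matrix_gives_one(self):
        assert qwk_statistic(np.diag([4, 9, 2])) == pytest.approx(1.0)

    def test_weight_matrix_three_classes(self):
        expected = np.array([[0, 0.25, 1], [0.25, 0, 0.25], [1, 0.25, 0]])
        np.testing.assert_allclose(qwk_weight_matrix(3), expected)
        np.testing.assert_allclose(qwk_weight_matrix(2), [[0, 1], [1, 0]])
        assert np.diag(qwk_weight_matrix(5)).sum() == 0

    def test_weight_matrix_needs_two_classes(self):
        with pytest.raises(ValueError):
            qwk_weight_matrix(1)

    @settings(max_examples=60, deadline=None)
    @given(count_matrices)
    def test_matches_brute_force_double_loop(self, counts):
        assert qwk_statistic(counts) == pytest.approx(brute_force_qwk(counts), abs=1e-12)

    def test_rejects_others_class(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int), ("NNeo", "LSIL", "HSIL", OTHERS))
        with pytest.raises(ValueError, match="ordinal"):
            qwk_statistic(cm)


class TestExcludeClass:
    def test_drops_row_and_column(self):
        """Slides predicted as the excluded class leave the evaluation."""
        t8 = ConfusionMatrix(
            np.array([[126, 21, 0, 22], [73, 202, 24, 16], [5, 25, 56, 0], [0, 2, 0, 28]]),
            ("NNeo", "LSIL", "HSIL", OTHERS))
        cm3 = exclude_class(t8, OTHERS)
        assert cm3.classes == ("NNeo", "LSIL", "HSIL")
        # the 2 LSIL slides predicted as non-representative are dropped
        np.testing.assert_array_equal(cm3.actual_totals, [204, 248, 80])
        assert t8.total - cm3.total == 22 + 16 + 0 + 28 + 2 + 0

    def test_zero_count_class_leaves_rest_unchanged(self):
        counts = np.array([[3, 1, 0], [0, 4, 0], [0, 0, 0]])
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        np.testing.assert_array_equal(exclude_class(cm, "c").counts, counts[:2, :2])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            exclude_class(ConfusionMatrix(np.eye(2, dtype=int), ("a", "b")), "z")


class TestSegmentationMetrics:
    def test_identical_masks_are_perfect(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 3:9] = True
        assert all(v == 1.0 for v in segmentation_metrics(m, m).values())

    def test_disjoint_masks(self):
        a = np.zeros((4, 8), bool)
        b = np.zeros((4, 8), bool)
        a[:, :4] = True
        b[:, 4:] = True
        out = segmentation_metrics(a, b)
        assert out["dice"] == 0.0 and out["iou"] == 0.0

    def test_empty_vs_empty_defined_as_perfect(self):
        z = np.zeros((5, 5), bool)
        out = segmentation_metrics(z, z)
        assert out["dice"] == 1.0 and out["iou"] == 1.0

    def test_shifted_strip_matches_counting_oracle(self):
        true = np.zeros((10, 100), bool)
        true[:, 10:90] = True
        pred = np.roll(true, 1, axis=1)
        tp = (true & pred).sum()
        expected = 2 * tp / (true.sum() + pred.sum())
        assert segmentation_metrics(pred, true)["dice"] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDetection:
    def test_perfect(self):
        assert detection_balanced_accuracy([True, True, False], [True, True, False]) == 1.0

    def test_all_predicted_positive_is_half(self):
        assert detection_balanced_accuracy([True] * 4, [True, True, False, False]) == 0.5

    def test_printed_cohort_counts(self):
        """534 positive slides with 532 detected; 28 of 66 negatives kept empty."""
        pred = [True] * 532 + [False] * 2 + [True] * 38 + [False] * 28
        act = [True] * 534 + [False] * 66
        expected = (532 / 534 + 28 / 66) / 2
        assert detection_balanced_accuracy(pred, act) == pytest.approx(expected)
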