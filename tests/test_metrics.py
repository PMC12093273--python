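"""Evaluation formulas vs. independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from somamapper.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    auc,
    avg_euclidean_distance,
    classification_metrics,
    detection_metrics,
    dice,
)
from tests.test_detect import exhaustive_match


def pairwise_auc(scores, labels):
    """O(n^2) oracle: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_counts(self):
        out = classification_metrics(ConfusionCounts(5, 5, 0, 0))
        assert out == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_all_wrong(self):
        out = classification_metrics(ConfusionCounts(0, 0, 5, 5))
        assert out["accuracy"] == 0 and out["sensitivity"] == 0 and out["specificity"] == 0

    def test_hand_arithmetic(self):
        out = classification_metrics(ConfusionCounts(3, 4, 2, 1))
        assert out["accuracy"] == pytest.approx(0.7)
        assert out["sensitivity"] == pytest.approx(0.75)
        assert out["specificity"] == pytest.approx(2 / 3)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics(ConfusionCounts(0, 5, 5, 0))  # no positives
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    def test_bounded_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 30, 4)
            out = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert all(0 <= v <= 1 for v in out.values())


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding creates ties
            ours = auc(scores, labels)
            assert ours == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(3 * scores), labels), abs=1e-12)


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(3).random((5, 5, 5)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, :2, :] = True  # 8 voxels
        b[0, 1:3, :] = True  # 8 voxels, 4 shared
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = np.zeros((3, 3, 3), bool)
        full = ~empty
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0

    def test_symmetry_and_set_arithmetic_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.random((6, 6, 6)) > 0.6
            b = rng.random((6, 6, 6)) > 0.6
            sa = {tuple(i) for i in np.argwhere(a)}
            sb = {tuple(i) for i in np.argwhere(b)}
            expected = 1.0 if not sa and not sb else \
                2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice(a, b) == pytest.approx(expected)
            assert dice(a, b) == dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAvgEuclideanDistance:
    def test_exact_prediction_zero(self):
        pts = [(1, 2, 3), (4, 5, 6)]
        assert avg_euclidean_distance(pts, pts) == 0.0

    def test_three_four_five_triangle(self):
        assert avg_euclidean_distance([(0, 0, 0)], [(3, 4, 0)], diff=10) == pytest.approx(5.0)

    def test_no_match_raises(self):
        with pytest.raises(UndefinedMetricError):
            avg_euclidean_distance([(0, 0, 0)], [(100, 0, 0)], diff=10)

    def test_bounded_by_threshold_and_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            gt = rng.uniform(0, 15, (int(rng.integers(1, 6)), 3))
            pred = rng.uniform(0, 15, (int(rng.integers(1, 6)), 3))
            card, total = exhaustive_match(gt, pred, 10.0)
            if card == 0:
                with pytest.raises(UndefinedMetricError):
                    avg_euclidean_distance(gt, pred, diff=10.0)
                continue
            value = avg_euclidean_distance(gt, pred, diff=10.0)
            assert value == pytest.approx(total / card, abs=1e-9)
            assert value <= 10.0


class TestDetectionMetrics:
    def test_perfect_detection_both_modes(self):
        for mode in ("as_printed", "conventional"):
            out = detection_metrics(10, 10, 10, convention=mode)
            assert out["precision"] == out["recall"] == out["f1"] == 1.0

    def test_as_printed_swaps_roles(self):
        out = detection_metrics(10, 8, 8, convention="as_printed")
        assert out["precision"] == pytest.approx(0.8)  # NTP / NGT
        assert out["recall"] == pytest.approx(1.0)     # NTP / Ndetected
        assert out["f1"] == pytest.approx(2 * 0.8 * 1.0 / 1.8)
        conv = detection_metrics(10, 8, 8, convention="conventional")
        assert conv["precision"] == pytest.approx(1.0)
        assert conv["recall"] == pytest.approx(0.8)

    def test_f1_invariant_under_mode_swap(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n_gt = int(rng.integers(1, 40))
            n_det = int(rng.integers(1, 40))
            n_tp = int(rng.integers(0, min(n_gt, n_det) + 1))
            a = detection_metrics(n_gt, n_tp, n_det, "as_printed")
            b = detection_metrics(n_gt, n_tp, n_det, "conventional")
            assert a["f1"] == pytest.approx(b["f1"], abs=1e-12)
            if a["precision"] > 0 and a["recall"] > 0:
                assert min(a["precision"], a["recall"]) <= a["f1"] <= \
                    max(a["precision"], a["recall"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics(5, 6, 5)
        with pytest.raises(UndefinedMetricError):
            detection_metrics(0, 0, 5)
        with pytest.raises(ValueError):
            detection_metrics(5, 5, 5, convention="other")
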