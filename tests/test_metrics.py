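"""Metric definitions against hand counts and the sklearn reference."""

import numpy as np
import pytest
import sklearn.metrics as skm

from sharkfuse.metrics import (
    BinaryCounts,
    accuracy_confidence_interval,
    auc_trapezoid,
    binary_metrics,
    confusion_matrix,
    full_report,
    one_vs_rest_counts,
    roc_curve,
)
from tests.conftest import random_probability_matrix

HAND_TRUE = [0, 0, 1, 1, 2, 2]
HAND_PRED = [0, 1, 1, 1, 2, 0]
HAND_CM = [[1, 1, 0], [0, 2, 0], [1, 0, 1]]


class TestConfusionMatrix:
    def test_hand_tabulation(self):
        cm = confusion_matrix(HAND_TRUE, HAND_PRED, 3)
        assert cm.counts.tolist() == HAND_CM

    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.integers(0, 3, 50)
        cm = confusion_matrix(y, y, 3)
        assert np.all(cm.counts == np.diag(np.bincount(y, minlength=3)))

    def test_total_conserved(self, rng):
        y_true = rng.integers(0, 4, 33)
        y_pred = rng.integers(0, 4, 33)
        assert confusion_matrix(y_true, y_pred, 4).counts.sum() == 33

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)


class TestOneVsRest:
    def test_hand_counts_class0(self):
        cm = confusion_matrix(HAND_TRUE, HAND_PRED, 3)
        c = one_vs_rest_counts(cm, 0)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 3)

    def test_perfect_diagonal_has_no_errors(self):
        cm = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
        for k in range(3):
            c = one_vs_rest_counts(cm, k)
            assert c.fp == 0 and c.fn == 0

    def test_conservation_per_class(self, rng):
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        cm = confusion_matrix(y_true, y_pred, 3)
        for k in range(3):
            c = one_vs_rest_counts(cm, k)
            assert c.tp + c.tn + c.fp + c.fn == 40


class TestBinaryMetrics:
    def test_direct_arithmetic(self):
        m = binary_metrics(BinaryCounts(tp=50, tn=40, fp=5, fn=5))
        assert m["accuracy"] == pytest.approx(0.90)
        assert m["precision"] == pytest.approx(0.9091, abs=5e-5)
        assert m["sensitivity"] == pytest.approx(0.9091, abs=5e-5)
        assert m["specificity"] == pytest.approx(0.8889, abs=5e-5)
        assert m["f1"] == pytest.approx(0.9091, abs=5e-5)

    def test_perfect_positive_only_case(self):
        # no negatives exist, so specificity is 0/0 and falls to the zero-rule;
        # the four defined statistics are all perfect
        m = binary_metrics(BinaryCounts(tp=10, tn=0, fp=0, fn=0))
        for k in ("accuracy", "precision", "sensitivity", "f1"):
            assert m[k] == 1.0
        assert m["specificity"] == 0.0

    def test_perfect_case_with_negatives(self):
        m = binary_metrics(BinaryCounts(tp=10, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_rule(self):
        m = binary_metrics(BinaryCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["precision"] == 0.0 and m["f1"] == 0.0


class TestROC:
    def test_perfect_separation_hits_corner(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert [0.0, 1.0] in curve.points.tolist()
        assert auc_trapezoid(curve) == 1.0

    def test_identical_scores_is_diagonal(self):
        curve = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.points.tolist() == [[0.0, 0.0], [1.0, 1.0]]
        assert auc_trapezoid(curve) == 0.5

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        assert curve.points[0].tolist() == [0.0, 0.0]
        assert curve.points[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(curve.points[:, 0]) >= 0)
        assert np.all(np.diff(curve.points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_hand_counted_pair_case(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.2}: 3 of 4 pairs concordant
        curve = roc_curve([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc_trapezoid(curve) == pytest.approx(0.75)

    def test_auc_equals_concordant_pair_statistic(self, rng):
        """Mann-Whitney equivalence for distinct scores."""
        for _ in range(20):
            scores = rng.permutation(np.linspace(0, 1, 25))
            labels = rng.integers(0, 2, 25)
            labels[:2] = [0, 1]
            pos, neg = scores[labels == 1], scores[labels == 0]
            mw = np.mean([p > q for p in pos for q in neg])
            auc = auc_trapezoid(roc_curve(scores, labels))
            assert abs(auc - mw) < 1e-12


class TestAgainstReference:
    def test_all_statistics_match_sklearn(self):
        """100 seeded random 3-class instances, equality within 1e-9."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.integers(0, 3, 200)
            probs = random_probability_matrix(rng, 200)
            rep = full_report(probs, y)
            pred = probs.argmax(axis=1)
            assert rep.accuracy == pytest.approx(skm.accuracy_score(y, pred), abs=1e-9)
            assert rep.precision == pytest.approx(
                skm.precision_score(y, pred, average="macro", zero_division=0), abs=1e-9)
            assert rep.sensitivity == pytest.approx(
                skm.recall_score(y, pred, average="macro", zero_division=0), abs=1e-9)
            assert rep.f1 == pytest.approx(
                skm.f1_score(y, pred, average="macro", zero_division=0), abs=1e-9)
            # specificity = recall of the negative class, averaged one-vs-rest
            specs = [skm.recall_score(y != k, pred != k, zero_division=0) for k in range(3)]
            assert rep.specificity == pytest.approx(np.mean(specs), abs=1e-9)
            assert rep.auc == pytest.approx(
                skm.roc_auc_score(y, probs, multi_class="ovr", average="macro"), abs=1e-9)

    def test_roc_curve_matches_sklearn(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        fpr, tpr, _ = skm.roc_curve(labels, scores, drop_intermediate=False)
        curve = roc_curve(scores, labels)
        np.testing.assert_allclose(curve.points[:, 0], fpr, atol=1e-12)
        np.testing.assert_allclose(curve.points[:, 1], tpr, atol=1e-12)


class TestFullReport:
    def test_perfect_probabilities(self):
        y = np.repeat([0, 1, 2], 5)
        probs = np.zeros((15, 3))
        probs[np.arange(15), y] = 1.0
        rep = full_report(probs, y, ("normal", "benign", "malignant"))
        for m in ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc"):
            assert getattr(rep, m) == 1.0

    def test_accuracy_is_pooled_trace(self, rng):
        y = np.r_[np.zeros(40, int), np.ones(5, int), np.full(5, 2)]
        probs = random_probability_matrix(rng, 50)
        rep = full_report(probs, y)
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion.counts) / 50)

    def test_values_in_unit_interval_and_relabel_invariance(self, rng):
        y = rng.integers(0, 3, 90)
        probs = random_probability_matrix(rng, 90)
        rep = full_report(probs, y)
        for m in ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc"):
            assert 0.0 <= getattr(rep, m) <= 1.0
        # permuting class identities permutes per-class stats, keeps macro values
        perm = np.array([2, 0, 1])  # new column j carries old class perm[j]
        inv = np.empty(3, int)
        inv[perm] = np.arange(3)
        rep_p = full_report(probs[:, perm], inv[y])
        for m in ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc"):
            assert getattr(rep_p, m) == pytest.approx(getattr(rep, m), abs=1e-12)

    def test_json_serialization_stable(self, rng):
        y = rng.integers(0, 3, 30)
        probs = random_probability_matrix(rng, 30)
        assert full_report(probs, y).to_json() == full_report(probs, y).to_json()


class TestConfidenceInterval:
    def test_degenerate_all_correct(self):
        assert accuracy_confidence_interval(np.ones(20)) == (1.0, 1.0)

    def test_contains_point_estimate(self, rng):
        flags = rng.integers(0, 2, 50)
        lo, hi = accuracy_confidence_interval(flags, n_boot=500, seed=3)
        assert lo <= flags.mean() <= hi

    def test_width_shrinks_with_n(self):
        widths = {n: [] for n in (100, 1000)}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            for n in widths:
                flags = (rng.random(n) < 0.8).astype(float)
                lo, hi = accuracy_confidence_interval(flags, n_boot=500, seed=seed)
                widths[n].append(hi - lo)
        assert np.mean(widths[1000]) < np.mean(widths[100])

    def test_seed_determinism(self, rng):
        flags = rng.integers(0, 2, 40)
        assert accuracy_confidence_interval(flags, seed=7) == accuracy_confidence_interval(
            flags, seed=7
        )
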