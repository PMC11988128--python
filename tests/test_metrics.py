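"""Evaluation metrics against brute-force oracles and library cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from hanrisk.metrics import (PredictionSet, auprc, auroc, bootstrap_ci,
                             bootstrap_diff_test, brier, calibration_curve,
                             evaluate_predictions, number_needed_to_test,
                             threshold_metrics)


def pset(labels, probs):
    labels = np.asarray(labels)
    return PredictionSet([f"p{i}" for i in range(len(labels))], labels,
                         np.asarray(probs, dtype=float))


def brute_auroc(labels, probs):
    """Exhaustive pair counting: P(case > control) + half ties."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_auprc(labels, probs):
    """Step sum over descending unique thresholds."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    thresholds = sorted(set(probs), reverse=True)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = probs >= t
        tp = int((labels[sel] == 1).sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc(pset([1, 0], [0.9, 0.1])) == 1.0

    def test_complete_ties(self):
        assert auroc(pset([1, 0, 1, 0], [0.3] * 4)) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc(pset([1, 1], [0.2, 0.3]))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            p = np.round(rng.random(n), 2)  # induce ties
            assert auroc(pset(y, p)) == pytest.approx(
                brute_auroc(y, p), abs=1e-12)

    def test_flip_label_identity(self, rng):
        """auroc(y) + auroc(1-y) = 1 for tie-free scores."""
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        p = rng.permutation(np.linspace(0.01, 0.99, 30))
        assert auroc(pset(y, p)) + auroc(pset(1 - y, p)) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40)
        assert auroc(pset(y, p)) == pytest.approx(auroc(pset(y, p ** 3)))


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc(pset([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_constant_scores_equal_prevalence(self):
        assert auprc(pset([1, 0, 0, 0], [0.5] * 4)) == pytest.approx(0.25)

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            auprc(pset([0, 0], [0.1, 0.2]))

    def test_20_point_fixture_matches_enumeration(self, rng):
        y = rng.integers(0, 2, 20)
        y[0] = 1
        p = np.round(rng.random(20), 1)
        assert auprc(pset(y, p)) == pytest.approx(brute_auprc(y, p), abs=1e-12)

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 25)
            y[0] = 1
            p = rng.random(25)
            assert auprc(pset(y, p)) == pytest.approx(
                average_precision_score(y, p), abs=1e-12)


class TestBrier:
    def test_perfect(self):
        assert brier(pset([1, 0], [1.0, 0.0])) == 0.0

    def test_hand_computed(self):
        assert brier(pset([0, 1], [0.2, 0.7])) == pytest.approx(0.065)

    def test_half_everywhere(self, rng):
        y = rng.integers(0, 2, 10)
        assert brier(pset(y, [0.5] * 10)) == 0.25

    def test_order_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert brier(pset(y, p)) == pytest.approx(brier(pset(y[perm], p[perm])))


class TestThresholdMetrics:
    def test_degenerate_cutoff(self):
        m = threshold_metrics(pset([1, 0, 1], [0.3, 0.2, 0.9]), cutoff=0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_confusion_fixture(self):
        # TP=3 FP=97 FN=1 TN=899
        y = [1] * 3 + [0] * 97 + [1] + [0] * 899
        p = [0.5] * 100 + [0.001] * 900
        m = threshold_metrics(pset(y, p), cutoff=0.004)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(899 / 996)
        assert m["ppv"] == pytest.approx(0.03)
        assert m["npv"] == pytest.approx(899 / 900)

    def test_undefined_cell_is_nan_not_zero(self):
        m = threshold_metrics(pset([1, 0], [0.001, 0.002]), cutoff=0.5)
        assert np.isnan(m["ppv"])  # no predicted positives

    def test_number_needed_to_test(self):
        assert number_needed_to_test(0.034) == 29


class TestCalibration:
    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.3, 5000)
        y = (rng.random(5000) < p).astype(int)
        curve = calibration_curve(pset(y, p))
        dev = np.abs(curve[:, 1] - curve[:, 0])
        assert dev.max() <= 0.05

    def test_constant_probability_flat_curve(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        curve = calibration_curve(pset(y, [0.25] * 200))
        assert np.allclose(curve[:, 1], y.mean(), atol=1e-9)

    def test_abscissae_below_trim(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 500)
        y = (rng.random(500) < p).astype(int)
        curve = calibration_curve(pset(y, p), trim=0.30)
        assert np.all(curve[:, 0] <= 0.30)

    def test_all_above_trim_raises(self):
        with pytest.raises(ValueError):
            calibration_curve(pset([0, 1] * 10, [0.9] * 20))


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        pred = pset([1, 0, 1, 0], [0.8, 0.1, 0.7, 0.2])
        point, lo, hi = bootstrap_ci(pred, lambda p: 0.42, n_boot=100, seed=0)
        assert point == lo == hi == 0.42

    def test_mean_ci_close_to_analytic(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(size=200)
        scaled = (draws - draws.min()) / (draws.max() - draws.min())
        pred = pset([0, 1] * 100, scaled)
        point, lo, hi = bootstrap_ci(
            pred, lambda p: float(p.probabilities.mean()),
            n_boot=1000, seed=7, need_both_classes=False)
        se = scaled.std(ddof=1) / np.sqrt(200)
        assert lo == pytest.approx(point - 1.96 * se, abs=0.1 * 2 * 1.96 * se)
        assert hi == pytest.approx(point + 1.96 * se, abs=0.1 * 2 * 1.96 * se)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(8)
        pred = pset(rng.integers(0, 2, 50), rng.random(50))
        a = bootstrap_ci(pred, brier, n_boot=200, seed=1)
        assert a == bootstrap_ci(pred, brier, n_boot=200, seed=1)

    def test_interval_ordered(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        pred = pset(y, rng.random(60))
        _, lo, hi = bootstrap_ci(pred, auroc, n_boot=200, seed=2)
        assert lo <= hi


class TestDiffTest:
    def _pair(self, n=200, seed=10):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        return y, rng.random(n)

    def test_identical_models_not_significant(self):
        y, p = self._pair()
        a, b = pset(y, p), pset(y, p)
        diff, lo, hi, sig = bootstrap_diff_test(a, b, auroc, n_boot=200, seed=0)
        assert diff == 0.0 and lo <= 0.0 <= hi and not sig

    def test_opposed_models_significant(self):
        y, _ = self._pair()
        p_good = 0.8 * y + 0.1
        p_bad = 1.0 - p_good
        a, b = pset(y, p_good), pset(y, p_bad)
        diff, lo, hi, sig = bootstrap_diff_test(a, b, auroc, n_boot=500, seed=1)
        assert sig and diff > 0

    def test_mismatched_patients_raise(self):
        y, p = self._pair(20)
        a = pset(y, p)
        b = PredictionSet([f"q{i}" for i in range(20)], y, p)
        with pytest.raises(ValueError):
            bootstrap_diff_test(a, b, auroc)


def test_full_report_structure(rng):
    y = rng.integers(0, 2, 300)
    y[:3] = [0, 1, 1]
    p = np.clip(0.3 * y + rng.random(300) * 0.4, 0, 1)
    report = evaluate_predictions(pset(y, p), cutoff=0.3, n_boot=100, seed=0)
    d = report.as_dict()
    for metric in ("auroc", "auprc", "brier", "sensitivity",
                   "specificity", "ppv", "npv"):
        t = d[metric]
        assert t["ci_low"] <= t["ci_high"]
    assert d["brier_x100"]["point"] == pytest.approx(100 * d["brier"]["point"])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1),
                          st.floats(0.0, 1.0, allow_nan=False)),
                min_size=4, max_size=40))
def test_rank_metric_properties_hold_on_arbitrary_inputs(pairs):
    """AUROC equals pair counting and respects the flip identity on any
    two-class instance; AUPRC equals the threshold enumeration."""
    y = np.array([a for a, _ in pairs])
    p = np.array([b for _, b in pairs])
    if y.sum() in (0, len(y)):
        y[0], y[1] = 0, 1
    ps = pset(y, p)
    assert auroc(ps) == pytest.approx(brute_auroc(y, p), abs=1e-12)
    assert auprc(ps) == pytest.approx(brute_auprc(y, p), abs=1e-12)
    if len(set(p)) == len(p):
        assert auroc(ps) + auroc(pset(1 - y, p)) == pytest.approx(1.0)


def test_metric_oracle_equivalence_random_instances(rng):
    """Rank metrics equal brute-force enumeration on many small instances."""
    for _ in range(200):
        n = int(rng.integers(4, 51))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        p = np.round(rng.random(n), int(rng.integers(1, 4)))
        ps = pset(y, p)
        assert auroc(ps) == pytest.approx(brute_auroc(y, p), abs=1e-12)
        assert auprc(ps) == pytest.approx(brute_auprc(y, p), abs=1e-12)
        assert brier(ps) == pytest.approx(np.mean((p - y) ** 2), abs=1e-12)
        if len(set(p)) == n:
            assert auroc(ps) == pytest.approx(roc_auc_score(y, p), abs=1e-12)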