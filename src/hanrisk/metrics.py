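"""Evaluation protocol for rare-outcome risk models.

Discrimination (AUROC as the Mann-Whitney pair statistic), precision-recall
(AUPRC as average precision with step interpolation), probability accuracy
(Brier score, reported x100 in tables), threshold metrics at a probability
cut-off equal to the outcome prevalence (default 0.004), LOWESS calibration
curves trimmed at 0.30, percentile bootstrap confidence intervals with 1000
resamples, and paired bootstrap significance tests on metric differences.

Average precision is used for AUPRC deliberately: trapezoidal interpolation
of the PR curve is known to over-estimate the area, so the two estimators
can differ on the same predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = ["PredictionSet", "MetricReport", "auroc", "auprc", "brier",
           "threshold_metrics", "number_needed_to_test", "calibration_curve",
           "bootstrap_ci", "bootstrap_diff_test", "evaluate_predictions",
           "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 0.004


@dataclass
class PredictionSet:
    """Aligned patient ids, observed labels and predicted probabilities."""

    patient_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not (len(self.patient_ids) == len(self.labels)
                == len(self.probabilities)):
            raise ValueError("patient_ids, labels and probabilities must align")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    def take(self, idx: np.ndarray) -> "PredictionSet":
        return PredictionSet([self.patient_ids[i] for i in idx],
                             self.labels[idx], self.probabilities[idx])


# ----------------------------------------------------------------- metrics
def auroc(pred: PredictionSet) -> float:
    """P(score_case > score_control) + 0.5 P(tie), via midranks."""
    y, p = pred.labels, pred.probabilities
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(p)             # midranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def auprc(pred: PredictionSet) -> float:
    """Average precision over descending unique thresholds (step sum)."""
    y, p = pred.labels, pred.probabilities
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # threshold boundaries: last index within each tied score group
    last = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def brier(pred: PredictionSet) -> float:
    """Mean squared error of the predicted probabilities."""
    return float(np.mean((pred.probabilities - pred.labels) ** 2))


def threshold_metrics(pred: PredictionSet,
                      cutoff: float = DEFAULT_CUTOFF) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV at ``p >= cutoff`` (inclusive).

    A rate whose denominator is zero is reported as NaN (undefined), never 0.
    """
    y = pred.labels
    pos = pred.probabilities >= cutoff
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))

    def rate(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
    }


def number_needed_to_test(ppv: float) -> int:
    """Patients flagged high-risk per detected case: round(1/PPV)."""
    if not np.isfinite(ppv) or ppv <= 0:
        raise ValueError("PPV must be positive and finite")
    return int(round(1.0 / ppv))


def calibration_curve(pred: PredictionSet, trim: float = 0.30,
                      lowess_frac: float = 2 / 3) -> np.ndarray:
    """LOWESS of the outcome on predicted probabilities, below ``trim``.

    Returns an array of (predicted, observed) points sorted by the
    predicted probability; the ideal curve is the diagonal.
    """
    if len(pred) < 20:
        raise ValueError("calibration needs at least 20 predictions")
    keep = pred.probabilities <= trim
    if not np.any(keep):
        raise ValueError(f"no predicted probability at or below trim={trim}")
    p = pred.probabilities[keep]
    y = pred.labels[keep].astype(float)
    if np.ptp(p) == 0.0:
        # single-abscissa limit: the smoothed curve is flat at the event rate
        return np.array([[float(p[0]), float(y.mean())]])
    # it=0: robustness iterations would treat the rare 0/1 outcomes as
    # outliers and systematically shrink the curve toward the majority class
    fitted = _sm_lowess(y, p, frac=lowess_frac, it=0, return_sorted=True)
    return fitted  # columns: predicted (sorted), smoothed observed


# --------------------------------------------------------------- bootstrap
def _resample_indices(rng: np.random.Generator, labels: np.ndarray,
                      need_both: bool, max_tries: int = 1000) -> np.ndarray:
    n = len(labels)
    for _ in range(max_tries):
        idx = rng.integers(0, n, size=n)
        if not need_both or len(np.unique(labels[idx])) == 2:
            return idx
    raise RuntimeError("could not draw a two-class bootstrap resample")


def bootstrap_ci(pred: "PredictionSet | np.ndarray",
                 metric_fn: Callable,
                 n_boot: int = 1000, seed: int = 0,
                 need_both_classes: bool = True
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap: (point, 2.5th, 97.5th percentile).

    For a PredictionSet, (label, probability) pairs are resampled with
    replacement, without outcome stratification; resamples lacking one of
    the classes are redrawn so rank metrics stay defined.  A plain sample
    array may also be passed, with ``metric_fn`` a statistic on arrays.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(pred, PredictionSet):
        values = np.asarray(pred, dtype=float)
        point = float(metric_fn(values))
        stats = np.empty(n_boot)
        for b in range(n_boot):
            stats[b] = metric_fn(values[rng.integers(0, len(values),
                                                     size=len(values))])
        lo, hi = np.percentile(stats, [2.5, 97.5])
        return point, float(lo), float(hi)
    point = float(metric_fn(pred))
    both = need_both_classes and len(np.unique(pred.labels)) == 2
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = _resample_indices(rng, pred.labels, both)
        stats[b] = metric_fn(pred.take(idx))
    if np.all(np.isnan(stats)):
        return point, float("nan"), float("nan")
    lo, hi = np.nanpercentile(stats, [2.5, 97.5])
    return point, float(lo), float(hi)


def bootstrap_diff_test(pred_a: PredictionSet, pred_b: PredictionSet,
                        metric_fn: Callable[[PredictionSet], float],
                        n_boot: int = 1000, seed: int = 0
                        ) -> tuple[float, float, float, bool]:
    """Paired percentile bootstrap on the metric difference (A minus B).

    Both prediction sets must cover the same patients in the same order;
    each resample draws one index vector applied to both.  The difference is
    significant at p < 0.05 when 0 lies outside the 95% interval.
    """
    if pred_a.patient_ids != pred_b.patient_ids:
        raise ValueError("paired comparison requires identical patient sets")
    if not np.array_equal(pred_a.labels, pred_b.labels):
        raise ValueError("paired comparison requires identical labels")
    rng = np.random.default_rng(seed)
    diff = float(metric_fn(pred_a) - metric_fn(pred_b))
    both = len(np.unique(pred_a.labels)) == 2
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = _resample_indices(rng, pred_a.labels, both)
        diffs[b] = metric_fn(pred_a.take(idx)) - metric_fn(pred_b.take(idx))
    lo, hi = np.nanpercentile(diffs, [2.5, 97.5])
    significant = not (lo <= 0.0 <= hi)
    return diff, float(lo), float(hi), bool(significant)


# ------------------------------------------------------------------ report
@dataclass
class MetricReport:
    """Point estimates with percentile-bootstrap intervals, Table-style."""

    auroc: tuple[float, float, float]
    auprc: tuple[float, float, float]
    brier: tuple[float, float, float]          # raw scale
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    cutoff: float = DEFAULT_CUTOFF
    n_boot: int = 1000
    n: int = 0

    @property
    def brier_x100(self) -> tuple[float, float, float]:
        return tuple(100.0 * v for v in self.brier)

    def as_dict(self) -> dict:
        def triple(t):
            return {"point": t[0], "ci_low": t[1], "ci_high": t[2]}
        return {
            "auroc": triple(self.auroc),
            "auprc": triple(self.auprc),
            "brier": triple(self.brier),
            "brier_x100": triple(self.brier_x100),
            "sensitivity": triple(self.sensitivity),
            "specificity": triple(self.specificity),
            "ppv": triple(self.ppv),
            "npv": triple(self.npv),
            "cutoff": self.cutoff,
            "n_boot": self.n_boot,
            "n": self.n,
        }


def evaluate_predictions(pred: PredictionSet, cutoff: float = DEFAULT_CUTOFF,
                         n_boot: int = 1000, seed: int = 0) -> MetricReport:
    """Full evaluation with bootstrap intervals for every reported metric."""
    def thr(name):
        return lambda p: threshold_metrics(p, cutoff)[name]

    fields_ = {
        "auroc": (auroc, True),
        "auprc": (auprc, True),
        "brier": (brier, False),
        "sensitivity": (thr("sensitivity"), True),
        "specificity": (thr("specificity"), True),
        "ppv": (thr("ppv"), True),
        "npv": (thr("npv"), True),
    }
    out = {}
    for i, (name, (fn, need_both)) in enumerate(fields_.items()):
        out[name] = bootstrap_ci(pred, fn, n_boot=n_boot, seed=seed + i,
                                 need_both_classes=need_both)
    return MetricReport(cutoff=cutoff, n_boot=n_boot, n=len(pred), **out)
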