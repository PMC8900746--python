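"""Confusion-matrix metrics with exact binomial CIs, ROC/AUC, and
Youden-optimal cutoff selection."""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are predicted labels, columns are true labels."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, positive: str) -> tuple[int, int, int, int]:
        """Collapse to (TP, FN, FP, TN) for one class."""
        i = self.labels.index(positive)
        tp = int(self.counts[i, i])
        fn = int(self.counts[:, i].sum()) - tp
        fp = int(self.counts[i, :].sum()) - tp
        tn = self.n - tp - fn - fp
        return tp, fn, fp, tn


def confusion_matrix(
    predicted: Sequence[str], truth: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(predicted) == 0:
        raise ValueError("empty input")
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, t in zip(predicted, truth):
        if p not in index or t not in index:
            raise ValueError(f"label outside declared set: predicted={p!r}, truth={t!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(labels, counts)


@dataclass
class MetricWithCI:
    point: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.point <= self.hi <= 1):
            raise ValueError(f"metric/CI out of order: {self}")


@dataclass
class BinaryMetrics:
    """Sensitivity/specificity/PPV/NPV with exact 95% CIs.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """

    sensitivity: MetricWithCI | None
    specificity: MetricWithCI | None
    ppv: MetricWithCI | None
    npv: MetricWithCI | None


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    alpha = 1 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def _metric(successes: int, n: int, level: float) -> MetricWithCI | None:
    if n == 0:
        return None
    lo, hi = clopper_pearson_ci(successes, n, level)
    return MetricWithCI(successes / n, lo, hi)


def binary_metrics(
    cm: ConfusionMatrix, positive_class: str, level: float = 0.95
) -> BinaryMetrics:
    """One-vs-rest sensitivity, specificity, PPV, NPV with exact CIs."""
    tp, fn, fp, tn = cm.one_vs_rest(positive_class)
    return BinaryMetrics(
        sensitivity=_metric(tp, tp + fn, level),
        specificity=_metric(tn, tn + fp, level),
        ppv=_metric(tp, tp + fp, level),
        npv=_metric(tn, tn + fn, level),
    )


def binary_metrics_from_counts(
    tp: int, fn: int, fp: int, tn: int, level: float = 0.95
) -> BinaryMetrics:
    """Metrics straight from 2x2 counts (positive class first row/column)."""
    cm = ConfusionMatrix(["pos", "neg"], np.array([[tp, fp], [fn, tn]]))
    return binary_metrics(cm, "pos", level)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending; positive call is score > threshold
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], binary_labels: Sequence[int]) -> ROCResult:
    """ROC curve and AUC for score-ranked binary labels.

    The curve is swept over the distinct score values (positive call:
    score > threshold), and the AUC is the trapezoidal integral — equal to
    the Mann-Whitney U statistic normalized by n1*n0, with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    # thresholds: +inf then each distinct score descending -> operating
    # points from (0,0) to (1,1)
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    pos = s[y == 1]
    neg = s[y == 0]
    tpr = np.array([(pos > t).mean() if np.isfinite(t) else 0.0 for t in thresholds])
    fpr = np.array([(neg > t).mean() if np.isfinite(t) else 0.0 for t in thresholds])
    # last threshold = min score gives (1,1) only if min is shared; append
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr = np.append(tpr, 1.0)
        fpr = np.append(fpr, 1.0)
        thresholds = np.append(thresholds, -np.inf)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tpr, fpr, auc)


def optimal_cutoff_youden(roc: ROCResult) -> float:
    """Threshold maximizing Youden's J = TPR - FPR.

    Candidate cutoffs are midpoints between adjacent distinct score values
    (and just outside the extremes), so separable data yields a cutoff
    strictly inside the gap. Ties at max J break toward the larger cutoff
    (higher specificity).
    """
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    if finite.size == 0:
        raise ValueError("ROC has no finite thresholds")
    desc = np.sort(finite)[::-1]
    candidates = [desc[0] + 1.0]
    candidates += [(a + b) / 2 for a, b in zip(desc[:-1], desc[1:])]
    candidates.append(desc[-1] - 1.0)
    best_j = -np.inf
    best_t = candidates[0]
    for t in candidates:
        # the operating point of "score > t" is the first curve point whose
        # threshold is < t (thresholds are descending)
        idx = int(np.searchsorted(-roc.thresholds, -t, side="left"))
        idx = min(idx, len(roc.thresholds) - 1)
        j = roc.tpr[idx] - roc.fpr[idx]
        if j > best_j or (j == best_j and t > best_t):
            best_j = j
            best_t = t
    return float(best_t)
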