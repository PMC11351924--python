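"""Agreement and classification metrics.

Implements the evaluation suite used throughout: unweighted Cohen's kappa
``(p0 - pe) / (1 - pe)``, the textbook binary rates
(accuracy, sensitivity, specificity, precision, F1), a threshold-swept ROC
with trapezoidal AUC (equal to the Mann-Whitney rank statistic
``Pr(s+ > s-) + 0.5 Pr(tie)``), a stratified percentile-bootstrap AUC
confidence interval, and the screening-oriented specificity obtained when the
decision threshold is lowered until recall is exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is degenerate (e.g. kappa at pe=1)."""


@dataclass
class ConfusionMatrix:
    """Truth-by-prediction count grid (rows = truth, columns = prediction)."""

    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(cls, truth, pred, labels) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(truth, pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(labels=list(labels), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        if self.total == 0:
            raise UndefinedMetricError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.labels, name="truth"),
                            columns=pd.Index(self.labels, name="prediction"))


def kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa, (p0 - pe) / (1 - pe)."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    p0 = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    pe = float(row @ col) / (n * n)
    if math.isclose(pe, 1.0, abs_tol=1e-12):
        raise UndefinedMetricError("kappa undefined: expected agreement pe = 1 (single effective category)")
    return float((p0 - pe) / (1.0 - pe))


@dataclass
class BinaryRates:
    """Eqs.-style binary rates; a metric with a zero denominator is NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int


def binary_rates(cm: ConfusionMatrix, positive_label=1) -> BinaryRates:
    """Accuracy, sensitivity (recall), specificity, precision and F1 from a
    2x2 confusion matrix.

    ``positive_label`` names the positive class among ``cm.labels``.  Any rate
    whose denominator is zero is reported as NaN (with a warning); the rest of
    the report is still carried.
    """
    if len(cm.labels) != 2:
        raise ValueError("binary_rates requires a 2x2 confusion matrix")
    pos = cm.labels.index(positive_label)
    neg = 1 - pos
    tp = int(cm.counts[pos, pos])
    fn = int(cm.counts[pos, neg])
    fp = int(cm.counts[neg, pos])
    tn = int(cm.counts[neg, neg])

    def _rate(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
            return float("nan")
        return num / den

    acc = _rate(tp + tn, tp + tn + fp + fn, "accuracy")
    sens = _rate(tp, tp + fn, "sensitivity")
    spec = _rate(tn, tn + fp, "specificity")
    prec = _rate(tp, tp + fp, "precision")
    if any(map(math.isnan, (prec, sens))) or (prec + sens) == 0:
        if not (math.isnan(prec) or math.isnan(sens)):
            warnings.warn("F1 undefined (precision + sensitivity = 0); reported as NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return BinaryRates(accuracy=acc, sensitivity=sens, specificity=spec, precision=prec, f1=f1,
                       tp=tp, tn=tn, fp=fp, fn=fn)


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points swept over all score thresholds, ties grouped.

    Returns a frame with columns (threshold, fpr, tpr) from the permissive
    end (everything positive) to the strict end (nothing positive).
    """
    scores, labels = _check_binary(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    npos = int(y.sum())
    nneg = len(y) - npos
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(1 - y)[cut]
    thresholds = s[cut]
    tpr = np.r_[0.0, tps / npos]
    fpr = np.r_[0.0, fps / nneg]
    thr = np.r_[np.inf, thresholds]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoid rule over grouped thresholds."""
    pts = roc_curve(scores, labels)
    return float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))


def mann_whitney_auc(scores, labels) -> float:
    """Brute-force rank statistic Pr(s+ > s-) + 0.5 Pr(s+ = s-).

    Quadratic-time oracle form of the AUC; kept as an independent cross-check
    of :func:`roc_auc`.
    """
    scores, labels = _check_binary(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def auc_ci(scores, labels, reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Positives and negatives are resampled within class, so every replicate
    contains both classes by construction.  Deterministic given ``seed``.
    """
    scores, labels = _check_binary(scores, labels)
    if reps < 200:
        raise ValueError("reps must be >= 200 for a stable percentile interval")
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    stats = np.empty(reps)
    degenerate = 0
    for i in range(reps):
        take = np.r_[rng.choice(pos_idx, size=len(pos_idx), replace=True),
                     rng.choice(neg_idx, size=len(neg_idx), replace=True)]
        stats[i] = roc_auc(scores[take], labels[take])
    if degenerate > reps * 0.01:
        warnings.warn(f"{degenerate} degenerate bootstrap replicates were redrawn")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi))


def specificity_at_full_recall(scores, labels) -> float:
    """Specificity at the lowest threshold that still captures every positive.

    The threshold is the minimum score among true positives (predict positive
    when score >= threshold), so recall is fixed at 1; the statistic is the
    fraction of negatives still correctly rejected at that operating point.
    """
    scores, labels = _check_binary(scores, labels)
    thr = scores[labels == 1].min()
    neg = scores[labels == 0]
    return float(np.mean(neg < thr))


@dataclass
class MetricsReport:
    """Bundle of binary-task metrics for one endpoint (plus or severity)."""

    n: int
    rates: BinaryRates
    kappa: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    specificity_at_full_recall: float = float("nan")
    extra: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        d = {
            "n": self.n,
            "accuracy": self.rates.accuracy,
            "sensitivity": self.rates.sensitivity,
            "specificity": self.rates.specificity,
            "precision": self.rates.precision,
            "f1": self.rates.f1,
            "kappa": self.kappa,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "specificity_at_full_recall": self.specificity_at_full_recall,
        }
        d.update(self.extra)
        return pd.Series(d)
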