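"""Confusion-matrix metrics, ROC/PR curves, Youden thresholding, McNemar
comparison and the probability-to-alert-level mapping.

Conventions: the positive class is the distress (SARS-risk) class; scores
are positive-class probabilities; a score >= threshold predicts positive.
Undefined ratios follow the usual zero conventions (precision/recall 0 when
their denominator is 0; MCC 0 when any denominator factor vanishes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "confusion_metrics",
    "roc_points",
    "roc_auc",
    "pr_points",
    "pr_auc",
    "youden_threshold",
    "mcnemar_test",
    "alert_level",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    """Count the 2x2 confusion table for the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Threshold-dependent metric suite from a confusion table.

    Returns accuracy, tp_rate (recall/sensitivity), fp_rate, precision,
    recall, f1 (harmonic mean of precision and recall) and the Matthews
    correlation coefficient.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.n
    if n == 0:
        raise ValueError("empty confusion table")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    fp_rate = fp / (fp + tn) if fp + tn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "tp_rate": recall,
        "fp_rate": fp_rate,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def _check_scores_labels(scores, labels, positive):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    pos = labels == positive
    if not pos.any():
        raise ValueError(f"no instance of the positive class {positive!r}")
    if pos.all():
        raise ValueError("no instance of the negative class")
    return scores, pos


def roc_points(scores, labels, positive=True) -> np.ndarray:
    """ROC curve by descending-score sweep with tie grouping.

    Returns an array of (fpr, tpr, threshold) rows from (0, 0, +inf) through
    (1, 1, min score); tied scores move as one block.
    """
    scores, pos = _check_scores_labels(scores, labels, positive)
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    # indices where the score strictly drops: block boundaries
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(p)[idx]
    fps = np.cumsum(~p)[idx]
    n_pos, n_neg = int(p.sum()), int((~p).sum())
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thr = np.r_[np.inf, s[idx]]
    return np.column_stack([fpr, tpr, thr])


def roc_auc(scores, labels=None, positive=True) -> float:
    """Trapezoidal area under the ROC curve.

    Accepts either a precomputed curve from :func:`roc_points` or raw
    (scores, labels).
    """
    curve = scores if labels is None else roc_points(scores, labels, positive)
    curve = np.asarray(curve)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def pr_points(scores, labels, positive=True) -> np.ndarray:
    """Precision-recall curve points (recall, precision, threshold)."""
    scores, pos = _check_scores_labels(scores, labels, positive)
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(p)[idx]
    preds = idx + 1.0
    n_pos = int(p.sum())
    recall = tps / n_pos
    precision = tps / preds
    return np.column_stack([recall, precision, s[idx]])


def pr_auc(scores, labels=None, positive=True) -> float:
    """Area under the precision-recall curve by rightward step interpolation.

    Sums precision at each achieved recall level times the recall increment
    (average-precision style), which avoids the optimistic linear
    interpolation between PR points.
    """
    curve = scores if labels is None else pr_points(scores, labels, positive)
    curve = np.asarray(curve)
    recall, precision = curve[:, 0], curve[:, 1]
    drec = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drec))


def youden_threshold(scores, labels, positive=True) -> float:
    """Threshold maximizing Youden's J = TPR - FPR over the score sweep.

    Candidate thresholds are the realized scores (predict positive when
    score >= threshold); ties on J break toward the lowest threshold.
    """
    curve = roc_points(scores, labels, positive)
    fpr, tpr, thr = curve[:, 0], curve[:, 1], curve[:, 2]
    j = tpr - fpr
    finite = np.isfinite(thr)
    j, thr = j[finite], thr[finite]
    best = j.max()
    candidates = thr[j >= best - 1e-15]
    return float(candidates.min())


def mcnemar_test(b: int, c: int, method: str = "auto") -> tuple[float, float]:
    """McNemar's paired test on the two discordant cells.

    ``b`` and ``c`` count test instances where exactly one of the two
    compared classifiers is correct. ``method='exact'`` uses the two-sided
    binomial test on min(b, c) out of b + c at rate 1/2 (statistic =
    min(b, c)); ``method='chi2'`` uses the continuity-corrected chi-square
    statistic ``(|b - c| - 1)^2 / (b + c)`` with 1 df. ``'auto'`` selects
    exact when b + c < 25, chi-square otherwise. Returns (statistic,
    p-value); b = c = 0 gives (0, 1).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if method == "auto":
        method = "exact" if n < 25 else "chi2"
    if method == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
        return float(k), float(p)
    if method == "chi2":
        statistic = (abs(b - c) - 1.0) ** 2 / n
        return float(statistic), float(stats.chi2.sf(statistic, df=1))
    raise ValueError(f"unknown method {method!r}")


def alert_level(p: float, boundaries: tuple[float, float] = (0.3, 0.6)) -> str:
    """Map a risk probability to a clinical alert level.

    low when p < lower boundary, high when p > upper boundary, moderate
    otherwise (both boundaries map to moderate).
    """
    lower, upper = boundaries
    if not 0.0 < lower < upper < 1.0:
        raise ValueError("boundaries must be strictly increasing within (0, 1)")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p < lower:
        return "low"
    if p > upper:
        return "high"
    return "moderate"
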