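"""Classifier evaluation: accuracy, ROC curves, AUC, and the DeLong paired test.

The AUC is the Mann-Whitney statistic — the probability that a random
positive outscores a random negative, with half credit for ties — computed
in O(n log n) via midranks.  DeLong's method expresses each model's AUC as
an average of structural components (placement values), whose empirical
covariance across models yields the variance of an AUC difference on the
same samples; the paired z test follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "EvalResult",
    "ROCCurve",
    "DeLongResult",
    "EvaluationError",
    "accuracy",
    "roc_auc",
    "roc_curve",
    "delong_test",
    "evaluate_scores",
]


class EvaluationError(ValueError):
    pass


@dataclass
class EvalResult:
    accuracy: float
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray

    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    delta: float
    var_delta: float
    z: float
    p_value: float


def _check_scores_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1-D arrays")
    if scores.size == 0:
        raise EvaluationError("empty input")
    return scores, labels


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of samples where (score >= threshold) matches the label."""
    scores, labels = _check_scores_labels(scores, labels)
    return float(np.mean((scores >= threshold) == (labels == 1)))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling, in O(n log n)."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present for AUC")
    ranks = rankdata(scores)  # average ranks = midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels) -> ROCCurve:
    """ROC sweep over unique score thresholds (descending), from (0,0) to (1,1)."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order].astype(float)
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(1.0 - sorted_pos)
    # collapse tied thresholds: keep the last index of each tie block
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    idx = np.flatnonzero(last_of_block)
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    tpr = np.r_[0.0, tp[idx] / n_pos]
    fpr = np.r_[0.0, fp[idx] / n_neg]
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) structural components."""
    m, n = int(pos.sum()), int((~pos).sum())
    rank_all = rankdata(scores)
    rank_pos = rankdata(scores[pos])
    rank_neg = rankdata(scores[~pos])
    auc = float((rank_all[pos].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (rank_all[pos] - rank_pos) / n  # P(score_pos > random negative)
    v01 = 1.0 - (rank_all[~pos] - rank_neg) / m
    return auc, v10, v01


def delong_test(scores1, scores2, labels) -> DeLongResult:
    """DeLong paired test for two correlated AUCs measured on the same samples.

    The variance of ``AUC1 - AUC2`` combines the covariance matrices of the
    positive-side and negative-side structural components; the two-sided
    p-value uses the normal approximation.  When the variance is zero the
    test is degenerate: p = 1 if the AUCs agree, else p = 0 with a warning.
    """
    s1, labels = _check_scores_labels(scores1, labels)
    s2, _ = _check_scores_labels(scores2, labels)
    if s1.shape != s2.shape:
        raise EvaluationError("score vectors must have identical length")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise EvaluationError("both classes must be present")
    auc1, v10_1, v01_1 = _placements(s1, pos)
    auc2, v10_2, v01_2 = _placements(s2, pos)
    delta = auc1 - auc2
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]))
        s01 = np.cov(np.vstack([v01_1, v01_2]))
        cov = s10 / m + s01 / n
        var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    else:
        var = 0.0
    var = max(var, 0.0)
    if var == 0.0:
        if delta == 0.0:
            z, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero DeLong variance with nonzero AUC difference", stacklevel=2
            )
            z, p = np.inf if delta > 0 else -np.inf, 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc1, auc2, delta, var, float(z), p)


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalResult:
    """Accuracy and AUC of one score vector."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = int((labels == 1).sum())
    return EvalResult(
        accuracy=accuracy(scores, labels, threshold),
        auc=roc_auc(scores, labels),
        n_pos=pos,
        n_neg=labels.size - pos,
    )
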