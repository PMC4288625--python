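"""Validation-set performance: ROC/AUC, Youden threshold, confusion metrics.

Conventions: predictions are probabilities of IPF; a sample is called IPF
when its probability is >= the threshold (so a reported cutoff is itself
attainable); Youden ties resolve toward the larger, specificity-favoring
threshold. Rates with an empty denominator are reported as absent (None),
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PerformanceReport",
    "roc_auc",
    "roc_curve",
    "youden_threshold",
    "confusion_metrics",
    "wilcoxon_rank_sum",
    "evaluate_predictions",
]


def _validate(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probs and labels must be equal-length 1-D arrays")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return p, y


def roc_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability a random IPF sample outscores a random normal
    sample, with ties counting one half.
    """
    p, y = _validate(probs, labels)
    ranks = stats.rankdata(p)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(probs: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """(fpr, tpr, threshold) rows for every distinct observed probability."""
    p, y = _validate(probs, labels)
    thresholds = np.unique(p)[::-1]
    n1, n0 = int(y.sum()), int((1 - y).sum())
    rows = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        call = p >= t
        tpr = float(np.sum(call & (y == 1))) / n1
        fpr = float(np.sum(call & (y == 0))) / n0
        rows.append((fpr, tpr, float(t)))
    return np.asarray(rows)


def youden_threshold(probs: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the observed probabilities, calls are made at p >= t,
    and ties go to the largest threshold.
    """
    p, y = _validate(probs, labels)
    best_t, best_j = None, -np.inf
    for t in np.unique(p):
        call = p >= t
        sens = float(np.sum(call & (y == 1))) / y.sum()
        spec = float(np.sum(~call & (y == 0))) / (y.size - y.sum())
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = float(t), j
    return best_t, best_j


@dataclass(frozen=True)
class PerformanceReport:
    """Operating characteristics of the signature as a diagnostic test."""

    auc: float
    threshold: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    wilcoxon_p: Optional[float]
    confusion: tuple[int, int, int, int]     # (tp, fp, tn, fn)

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "auc": self.auc, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "wilcoxon_p": self.wilcoxon_p,
            "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        }


def _rate(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(probs: Sequence[float], labels: Sequence[int],
                      threshold: float) -> PerformanceReport:
    """Confusion counts and derived rates at a fixed probability cutoff.

    AUC and the Wilcoxon p are filled by :func:`evaluate_predictions`; here
    they are left as the threshold-free AUC and None respectively.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    p, y = _validate(probs, labels)
    call = p >= threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    return PerformanceReport(
        auc=roc_auc(p, y),
        threshold=float(threshold),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        accuracy=_rate(tp + tn, tp + fp + tn + fn),
        wilcoxon_p=None,
        confusion=(tp, fp, tn, fn),
    )


def wilcoxon_rank_sum(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Two-sided Wilcoxon rank-sum p for association of probability with phenotype.

    Exact enumeration when both groups have <= 10 observations and no ties;
    otherwise a tie-corrected normal approximation with a continuity
    correction that shrinks |U - mean| by 1/2 without crossing zero (so
    perfectly symmetric data gives p = 1).
    """
    p, y = _validate(probs, labels)
    a, b = p[y == 1], p[y == 0]
    no_ties = np.unique(p).size == p.size
    if a.size <= 10 and b.size <= 10 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(min(res.pvalue, 1.0))
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(p)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(p, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    z = max(abs(u - mean_u) - 0.5, 0.0) / np.sqrt(var_u)
    return float(min(2.0 * stats.norm.sf(z), 1.0))


def evaluate_predictions(probs: Sequence[float], labels: Sequence[int],
                         threshold: Optional[float] = None) -> PerformanceReport:
    """Full validation report: AUC, threshold (Youden unless fixed), rates, Wilcoxon p."""
    p, y = _validate(probs, labels)
    if threshold is None:
        threshold, _ = youden_threshold(p, y)
    base = confusion_metrics(p, y, threshold)
    return PerformanceReport(
        auc=base.auc, threshold=base.threshold,
        sensitivity=base.sensitivity, specificity=base.specificity,
        ppv=base.ppv, npv=base.npv, accuracy=base.accuracy,
        wilcoxon_p=wilcoxon_rank_sum(p, y), confusion=base.confusion,
    )
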