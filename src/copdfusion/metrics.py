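"""Binary-classification metrics with late-stage disease as the positive class.

Accuracy, precision, sensitivity, specificity and F1 follow the standard
confusion-count formulas; AUC is the rank (Mann-Whitney) statistic — the
probability that a random positive outscores a random negative, ties
counted one half.  Metrics with a zero denominator are reported as
undefined (``None``), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats as _sps

__all__ = ["ConfusionCounts", "MetricsRecord", "confusion_counts",
           "compute_metrics", "auc", "evaluate_scores"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRecord:
    acc: Optional[float]
    pre: Optional[float]
    sen: Optional[float]
    spe: Optional[float]
    f1: Optional[float]
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts,
                    auc_value: Optional[float] = None) -> MetricsRecord:
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    pre = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    f1 = None
    if pre is not None and sen is not None and (pre + sen) > 0:
        f1 = 2.0 * pre * sen / (pre + sen)
    return MetricsRecord(
        acc=_ratio(tp + tn, counts.n),
        pre=pre,
        sen=sen,
        spe=_ratio(tn, tn + fp),
        f1=f1,
        auc=auc_value,
    )


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = _sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def evaluate_scores(scores, y_true, threshold: float = 0.5) -> MetricsRecord:
    """Metrics from positive-class probabilities at the given threshold."""
    y_pred = (np.asarray(scores, float) > threshold).astype(int)
    counts = confusion_counts(y_true, y_pred)
    try:
        a = auc(scores, y_true)
    except ValueError:
        a = None
    return compute_metrics(counts, auc_value=a)
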