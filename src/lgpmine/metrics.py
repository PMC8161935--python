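"""Classification metrics for evolved models.

Accuracy is the fitness currency of the evolutionary search; F1 and AUC are
used to characterise collections of best-of-run models. The positive class
for precision/recall/F1 is label 1 (the disease class) unless stated
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predictions, labels, positive: int = 1):
        p = np.asarray(predictions)
        y = np.asarray(labels)
        if p.shape != y.shape:
            raise InvalidInputError("predictions and labels differ in length")
        pos_p, pos_y = p == positive, y == positive
        return cls(
            tp=int(np.sum(pos_p & pos_y)),
            fp=int(np.sum(pos_p & ~pos_y)),
            tn=int(np.sum(~pos_p & ~pos_y)),
            fn=int(np.sum(~pos_p & pos_y)),
        )


@dataclass(frozen=True)
class RocCurve:
    """FPR/TPR pairs over descending thresholds, from (0,0) to (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def precision(counts: ConfusionCounts) -> float:
    d = counts.tp + counts.fp
    return counts.tp / d if d else 0.0


def recall(counts: ConfusionCounts) -> float:
    d = counts.tp + counts.fn
    return counts.tp / d if d else 0.0


def f1_score(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = precision(counts), recall(counts)
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def accuracy(predictions, labels) -> float:
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape or p.size == 0:
        raise InvalidInputError("predictions and labels must be equal-length, nonempty")
    return float(np.mean(p == y))


def roc_curve(scores, labels) -> RocCurve:
    """ROC over all distinct score thresholds (descending), with sentinels."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with score ties counting one half.
    """
    curve = roc_curve(scores, labels)
    return float(np.trapezoid(curve.tpr, curve.fpr))
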