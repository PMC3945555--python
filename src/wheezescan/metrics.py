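"""Frame-level evaluation metrics.

Wheeze is the positive class.  Besides sensitivity and specificity, the
combined performance statistic PER is the geometric mean sqrt(SE * SP) — the
form consistent, to every printed digit, with published confusion tables for
this detector family (an arithmetic mean is not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConfusionCounts",
    "sensitivity",
    "specificity",
    "performance",
    "confusion",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero."""


def sensitivity(c: ConfusionCounts) -> float:
    """SE = TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive examples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """SP = TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative examples")
    return c.tn / (c.tn + c.fp)


def performance(c: ConfusionCounts) -> float:
    """PER = sqrt(SE * SP), the geometric mean."""
    return math.sqrt(sensitivity(c) * specificity(c))


def confusion(labels, predictions, positive: str = "wheeze") -> ConfusionCounts:
    """Tally a confusion matrix from parallel label/prediction sequences."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    tp = tn = fp = fn = 0
    for truth, pred in zip(labels, predictions):
        if truth == positive:
            if pred == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
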