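"""Classifier performance measures for site recognition.

With S positive examples (sites) and N negatives (non-sites) the
confusion counts TP, FP, TN, FN define

    Sn = TP / (TP + FN)                  (sensitivity, true positive rate)
    Sp = TN / (TN + FP)                  (specificity, true negative rate)
    AC = (TP + TN) / (TP + TN + FP + FN) (accuracy)
    CC = (TP*TN - FP*FN) /
         sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

CC is the Matthews-style correlation between predictions and labels; it
accounts for unequal class sizes where AC does not.  All metrics are
computed in double precision; nothing is rounded until display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DataError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise DataError(f"{name} must be a nonnegative integer, got {v!r}") from None
            if iv != v or iv < 0:
                raise DataError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        """Number of positive examples (S = TP + FN)."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Number of negative examples (N = TN + FP)."""
        return self.tn + self.fp


def tally(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tally confusion counts from parallel binary label/prediction lists.

    1 marks the positive (promoter) class.
    """
    if len(labels) != len(predictions):
        raise DataError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    if len(labels) == 0:
        raise DataError("cannot tally empty inputs")
    tp = fp = tn = fn = 0
    for y, p in zip(labels, predictions):
        if y not in (0, 1) or p not in (0, 1):
            raise DataError(f"labels/predictions must be binary, got ({y!r}, {p!r})")
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive examples (TP+FN = 0)")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative examples (TN+FP = 0)")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no examples")
    return (c.tp + c.tn) / c.total


def correlation_coefficient(c: ConfusionCounts, *, zero_on_degenerate: bool = False) -> float:
    """Matthews-style correlation coefficient.

    Any zero marginal sum makes the denominator vanish; by default this is
    an error (silent zeros hide broken evaluations).  Pass
    ``zero_on_degenerate=True`` to map that case to 0.0 explicitly.
    """
    marginals = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if 0 in marginals:
        if zero_on_degenerate:
            return 0.0
        raise UndefinedMetricError(
            f"correlation coefficient undefined: zero marginal in {marginals}"
        )
    num = c.tp * c.tn - c.fp * c.fn
    den = math.sqrt(math.prod(float(m) for m in marginals))
    return num / den


def summary(c: ConfusionCounts, *, zero_on_degenerate: bool = False) -> dict[str, float]:
    """All four measures plus the raw counts, as a flat dict."""
    return {
        "Sn": sensitivity(c),
        "Sp": specificity(c),
        "AC": accuracy(c),
        "CC": correlation_coefficient(c, zero_on_degenerate=zero_on_degenerate),
        "TP": c.tp,
        "FP": c.fp,
        "TN": c.tn,
        "FN": c.fn,
    }


def format_report(c: ConfusionCounts, *, decimals: int = 2, zero_on_degenerate: bool = False) -> str:
    """Key/value evaluation report; metric display rounds to 2 decimals by default."""
    s = summary(c, zero_on_degenerate=zero_on_degenerate)
    lines = [f"{k}\t{s[k]:.{decimals}f}" for k in ("Sn", "Sp", "AC", "CC")]
    lines += [f"{k}\t{int(s[k])}" for k in ("TP", "FP", "TN", "FN")]
    return "\n".join(lines)
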