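"""Performance measures with the indeterminate-exclusion convention.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/(TP+FN+TN+FP) and CCR = (sensitivity+specificity)/2, all expressed
as percentages. Indeterminate predictions (consensus score exactly zero)
cannot be tallied as right or wrong: they are counted separately and
excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import DegenerateTallyError, LengthMismatchError

_POSITIVE = {"sensitizer", "S", "+1", "1", 1}
_NEGATIVE = {"non-sensitizer", "N", "-1", -1}
_INDETERMINATE = {"indeterminate", "0", 0, None}


def _sign(value, *, allow_indeterminate: bool):
    # membership is checked on exact values; 0/False and 1/True compare
    # equal in Python, so indeterminate is resolved first
    if allow_indeterminate and value in _INDETERMINATE and value is not False:
        return 0
    if value in _POSITIVE:
        return 1
    if value in _NEGATIVE or value is False:
        return -1
    raise ValueError(f"unrecognized label {value!r}")


@dataclass(frozen=True)
class ConfusionTally:
    """Confusion counts plus the number of indeterminate predictions."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_indeterminate: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "n_indeterminate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_indeterminate

    @property
    def n_determinate(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _round2(x: float) -> float:
    """Display rounding: 2 decimals, half-up (matching printed tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PerformanceReport:
    """The four headline percentages, unrounded, plus display rounding."""

    sensitivity: float
    specificity: float
    accuracy: float
    ccr: float
    n_indeterminate: int = 0

    def rounded(self) -> dict[str, float]:
        return {
            "sensitivity": _round2(self.sensitivity),
            "specificity": _round2(self.specificity),
            "accuracy": _round2(self.accuracy),
            "ccr": _round2(self.ccr),
        }


def tally(predictions: Sequence, truth: Sequence) -> ConfusionTally:
    """Tally predictions against binary truth.

    Predictions may be ``sensitizer`` / ``non-sensitizer`` /
    ``indeterminate`` labels or +1 / -1 / 0; truth must be binary.
    Indeterminate predictions go to ``n_indeterminate`` and never into the
    four confusion cells.
    """
    if len(predictions) != len(truth):
        raise LengthMismatchError(
            f"{len(predictions)} predictions vs {len(truth)} truths"
        )
    if len(predictions) == 0:
        raise LengthMismatchError("empty inputs")
    tp = fp = tn = fn = n_ind = 0
    for p, t in zip(predictions, truth):
        t_sign = _sign(t, allow_indeterminate=False)
        p_sign = _sign(p, allow_indeterminate=True)
        if p_sign == 0:
            n_ind += 1
        elif t_sign == 1:
            tp += p_sign == 1
            fn += p_sign == -1
        else:
            tn += p_sign == -1
            fp += p_sign == 1
    return ConfusionTally(tp=tp, fp=fp, tn=tn, fn=fn, n_indeterminate=n_ind)


def compute_metrics(t: ConfusionTally) -> PerformanceReport:
    """Sensitivity, specificity, accuracy and CCR (percent) from a tally."""
    if t.tp + t.fn == 0 or t.tn + t.fp == 0:
        raise DegenerateTallyError(
            "each class needs at least one determinate prediction"
        )
    sensitivity = 100.0 * t.tp / (t.tp + t.fn)
    specificity = 100.0 * t.tn / (t.tn + t.fp)
    accuracy = 100.0 * (t.tp + t.tn) / t.n_determinate
    ccr = (sensitivity + specificity) / 2.0
    return PerformanceReport(
        sensitivity=sensitivity, specificity=specificity,
        accuracy=accuracy, ccr=ccr, n_indeterminate=t.n_indeterminate,
    )
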