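"""Family-specific allergenicity thresholds on epitope counts.

Within one protein family (here parvalbumins), highly allergenic members
accumulate many more mapped IgE epitopes than their less/non-allergenic
relatives.  A simple integer cut on the mismatch-tolerant positive count
(#positive IEDB-2M >= T, with T = 4 for parvalbumins) separates the two
classes.  This module scans for the balanced-accuracy-optimal T, classifies
counts against a threshold, reports capture rates, and runs Welch's
two-sample t-test (unequal variances, Satterthwaite degrees of freedom)
from summary statistics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .catalog import _round_half_up

__all__ = [
    "ThresholdError",
    "Label",
    "LabeledCount",
    "ThresholdResult",
    "WelchResult",
    "scan_threshold",
    "classify",
    "capture_rate",
    "welch_t_test",
]


class ThresholdError(ValueError):
    pass


class Label(str, enum.Enum):
    ALLERGENIC = "allergenic"
    LESS_NON_ALLERGENIC = "less_non_allergenic"


@dataclass(frozen=True)
class LabeledCount:
    """A sequence's mismatch-tolerant positive epitope count with its class."""

    sequence_id: str
    count: int
    label: Label

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ThresholdError(f"{self.sequence_id}: negative count")


@dataclass(frozen=True)
class ThresholdResult:
    threshold: int
    objective_value: float
    per_class_accuracy: tuple[float, float]  # (sensitivity, specificity)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_tailed: float


def classify(count: int, threshold: int) -> Label:
    """Counts at or above the threshold are allergenic (the cut is inclusive)."""
    if threshold < 0:
        raise ThresholdError("threshold must be >= 0")
    return Label.ALLERGENIC if count >= threshold else Label.LESS_NON_ALLERGENIC


def _balanced_accuracy(data: Sequence[LabeledCount], threshold: int) -> tuple[float, float, float]:
    pos = [d for d in data if d.label is Label.ALLERGENIC]
    neg = [d for d in data if d.label is Label.LESS_NON_ALLERGENIC]
    sens = sum(1 for d in pos if d.count >= threshold) / len(pos)
    spec = sum(1 for d in neg if d.count < threshold) / len(neg)
    return (sens + spec) / 2.0, sens, spec


def scan_threshold(data: Sequence[LabeledCount]) -> ThresholdResult:
    """Exhaustively scan T in 0..max(count)+1 for the best balanced accuracy.

    Balanced accuracy — the mean of sensitivity on the allergenic class and
    specificity on the less/non-allergenic class — is insensitive to the
    class imbalance typical of these panels.  Ties go to the smallest T so
    the result is deterministic.
    """
    labels = {d.label for d in data}
    if labels != {Label.ALLERGENIC, Label.LESS_NON_ALLERGENIC}:
        raise ThresholdError("both classes must be present to scan a threshold")
    best: ThresholdResult | None = None
    for t in range(0, max(d.count for d in data) + 2):
        obj, sens, spec = _balanced_accuracy(data, t)
        if best is None or obj > best.objective_value + 1e-12:
            best = ThresholdResult(t, obj, (sens, spec))
    assert best is not None
    return best


def capture_rate(counts: Sequence[int], threshold: int) -> tuple[int, int]:
    """How many counts reach the threshold: (n_captured, whole-percent fraction)."""
    if not counts:
        raise ThresholdError("empty count list")
    captured = sum(1 for c in counts if c >= threshold)
    pct = int(_round_half_up(100.0 * captured / len(counts), 0))
    return captured, pct


def welch_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's two-sample t-test from summary statistics.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2); degrees of freedom by
    Welch-Satterthwaite; the p-value is two-tailed.  Works from printed
    summaries (mean, SD, n per group), so no raw data are required.
    """
    if n1 < 2 or n2 < 2:
        raise ThresholdError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ThresholdError("degenerate variances: SDs must be >= 0 and not both 0")
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    se = math.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p_two_tailed=min(p, 1.0))
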