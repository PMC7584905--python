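"""Contingency and proportion statistics for binary judgment experiments.

Implemented from first principles (only the chi-square tail probability
comes from scipy) so every printed statistic is recomputable from the raw
counts: Pearson's chi-square for 2x2 tables with optional Yates continuity
correction, Cramér's V (= phi for 2x2), McNemar's test of changes for paired
binary responses, and small helpers for proportion differences, concordance
summaries, and the standard error of a proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "TwoByTwoTable",
    "PairedPatternCounts",
    "chi2_2x2",
    "cramers_v_from_chi2",
    "mcnemar",
    "proportion_difference",
    "concordance_summary",
    "sem_proportion",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """A 2x2 contingency table; rows are conditions, columns judgments.

    ::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all counts must be non-negative")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class PairedPatternCounts:
    """Paired binary responses to two stories: the two concordant counts and
    the two discordant ("switch") counts."""

    both_negative: int
    both_positive: int
    switch_expected: int
    switch_opposite: int

    def __post_init__(self) -> None:
        counts = (self.both_negative, self.both_positive,
                  self.switch_expected, self.switch_opposite)
        if min(counts) < 0:
            raise ValueError("all counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.both_negative + self.both_positive
                + self.switch_expected + self.switch_opposite)


def chi2_2x2(table: TwoByTwoTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence for a 2x2 table.

    Statistic ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with Yates'
    continuity correction, ``|ad - bc|`` is reduced by ``n/2`` (floored at 0)
    before squaring.  Returns (statistic, upper-tail p with 1 df).
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a margin of the table is zero")
    n = table.n
    det = table.a * table.d - table.b * table.c
    if yates:
        det = max(abs(det) - n / 2.0, 0.0)
    stat = n * float(det) ** 2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p


def cramers_v_from_chi2(chi2: float, n: int) -> float:
    """Cramér's V from a chi-square statistic and sample size; for a 2x2
    table this equals the phi coefficient, ``sqrt(chi2 / n)``."""
    if chi2 < 0:
        raise ValueError(f"chi2 must be non-negative, got {chi2}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return math.sqrt(chi2 / n)


def mcnemar(counts: PairedPatternCounts, continuity_correction: bool = True) -> tuple[float, float]:
    """McNemar's test of changes on the discordant pair counts.

    Statistic ``(|b - c| - 1)^2 / (b + c)`` with the continuity correction
    and ``(b - c)^2 / (b + c)`` without, where b and c are the two switch
    counts.  Returns (statistic, upper-tail p with 1 df).
    """
    b, c = counts.switch_expected, counts.switch_opposite
    if b + c == 0:
        raise ValueError("McNemar undefined: no discordant pairs")
    diff = abs(b - c)
    if continuity_correction:
        diff = max(diff - 1.0, 0.0)
    stat = diff**2 / (b + c)
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p


def proportion_difference(p_low: float, p_high: float) -> float:
    """Difference in acceptability proportions between conditions,
    ``p_low - p_high`` (e.g. low-interest minus high-interest)."""
    for name, p in (("p_low", p_low), ("p_high", p_high)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    return p_low - p_high


def concordance_summary(counts: PairedPatternCounts) -> dict:
    """Proportion of each paired response pattern plus the overall
    same-answer proportion."""
    total = counts.total
    if total == 0:
        raise ValueError("no paired responses")
    return {
        "both_negative": counts.both_negative / total,
        "both_positive": counts.both_positive / total,
        "switch_expected": counts.switch_expected / total,
        "switch_opposite": counts.switch_opposite / total,
        "same_answer": (counts.both_negative + counts.both_positive) / total,
    }


def sem_proportion(p: float, n: int) -> float:
    """Standard error of a sample proportion, ``sqrt(p (1 - p) / n)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return math.sqrt(p * (1.0 - p) / n)
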