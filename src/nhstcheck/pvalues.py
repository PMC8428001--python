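"""Recomputation of p-values and rounding-interval propagation.

Reference distributions: Student t (two-tailed) for t-tests; standard normal
(two-tailed) for Z; the correlation r is transformed to t = |r|·sqrt(df/(1-r²))
with df = n-2 and referred to a t distribution; F(df1, df2) is an upper tail;
chi-square and all heterogeneity Q-tests (omnibus, between, within) are
chi-square upper tails with the printed degrees of freedom — Cochran's Q is
chi-square distributed under homogeneity.  No continuity corrections.

A statistic printed as 2.35 stands for any actual value in [2.345, 2.355):
rounding-interval arithmetic propagates that interval through the tail
function, giving a band of p-values treated as compatible with the print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_FLOOR, Decimal
from typing import Optional, Tuple

from scipy import stats

from .extract import CHI_SQUARE_FAMILIES, ReportedNumber, TestFamily

__all__ = [
    "PInterval",
    "recompute_p",
    "statistic_interval",
    "p_interval",
    "truncate_p",
]


@dataclass(frozen=True)
class PInterval:
    """Recomputed p-value with the band induced by statistic rounding.

    ``p_point`` is the p-value at the statistic exactly as printed;
    ``[p_lo, p_hi]`` bounds the p-values attainable over the statistic's
    rounding interval.  Always ``0 <= p_lo <= p_point <= p_hi <= 1``.
    """

    p_point: float
    p_lo: float
    p_hi: float

    def __post_init__(self):
        if not 0.0 <= self.p_lo <= self.p_point <= self.p_hi <= 1.0:
            raise ValueError(
                f"invalid p interval: lo={self.p_lo} point={self.p_point} hi={self.p_hi}"
            )

    def halved(self) -> "PInterval":
        """The one-sided band: every two-tailed p divided by two."""
        return PInterval(self.p_point / 2.0, self.p_lo / 2.0, self.p_hi / 2.0)


def recompute_p(
    family: TestFamily,
    statistic: float,
    df1: Optional[float] = None,
    df2: Optional[float] = None,
) -> float:
    """Recompute the p-value for a test family from statistic and df.

    Two-tailed for t, Z, r (symmetric in the sign of the statistic);
    upper-tail for F, chi-square, and the Q family.  |r| = 1 gives p = 0
    (degenerate but well-defined).
    """
    if family is TestFamily.Z:
        return float(2.0 * stats.norm.sf(abs(statistic)))
    if family is TestFamily.t:
        if df1 is None:
            raise ValueError("t-test requires df1")
        return float(2.0 * stats.t.sf(abs(statistic), df1))
    if family is TestFamily.r:
        if df1 is None or df1 < 1:
            raise ValueError("correlation requires df1 >= 1 (df = n - 2)")
        r = abs(statistic)
        if r > 1.0:
            raise ValueError("|r| must be <= 1")
        if r == 1.0:
            return 0.0
        tval = r * math.sqrt(df1 / (1.0 - r * r))
        return float(2.0 * stats.t.sf(tval, df1))
    if family is TestFamily.F:
        if df1 is None or df2 is None:
            raise ValueError("F-test requires df1 and df2")
        return float(stats.f.sf(statistic, df1, df2))
    if family in CHI_SQUARE_FAMILIES:
        if df1 is None:
            raise ValueError(f"{family.value} requires df1")
        return float(stats.chi2.sf(statistic, df1))
    raise ValueError(f"unknown family {family!r}")  # pragma: no cover


def statistic_interval(statistic: ReportedNumber) -> Tuple[float, float]:
    """Rounding interval of a printed statistic.

    For ``=`` claims, a value printed with d decimals stands for the
    half-open interval [value - 5·10^-(d+1), value + 5·10^-(d+1)).  For
    ``<`` / ``>`` the implied one-sided interval is returned (open end at
    infinity).
    """
    if statistic.op == "=":
        half = 0.5 * 10.0 ** (-statistic.decimals)
        return (statistic.value - half, statistic.value + half)
    if statistic.op == "<":
        return (-math.inf, statistic.value)
    return (statistic.value, math.inf)


def p_interval(
    family: TestFamily,
    statistic: ReportedNumber,
    df1: Optional[float] = None,
    df2: Optional[float] = None,
) -> PInterval:
    """Propagate the statistic's rounding interval to a p-value band.

    Each family's tail function is monotone in |statistic|, so evaluating
    the interval endpoints suffices; when the interval straddles zero the
    maximum p (attained at statistic 0) is included.
    """
    p_point = recompute_p(family, statistic.value, df1, df2)
    lo, hi = statistic_interval(statistic)
    if math.isinf(lo) or math.isinf(hi):
        return _one_sided_band(statistic, p_point)
    p_a = recompute_p(family, lo, df1, df2)
    p_b = recompute_p(family, hi, df1, df2)
    p_lo = min(p_a, p_b, p_point)
    p_hi = max(p_a, p_b, p_point)
    if lo < 0.0 < hi:
        p_hi = 1.0  # |statistic| can be arbitrarily small inside the interval
    return PInterval(p_point, p_lo, p_hi)


def _one_sided_band(statistic: ReportedNumber, p_point: float) -> PInterval:
    # "stat < v": actual |statistic| below v, p anywhere in (p(v), 1];
    # "stat > v": p anywhere in [0, p(v)).  Rare in practice.
    if statistic.op == "<":
        return PInterval(p_point, p_point, 1.0)
    return PInterval(p_point, 0.0, p_point)


def truncate_p(p: float, decimals: int = 3) -> float:
    """Floor-truncate a p-value for display (.0499… prints as .049).

    Reporting convention only — internal comparisons always use full
    precision.  Decimal-based so binary float artifacts cannot flip the
    truncated digit.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(p)).quantize(q, rounding=ROUND_FLOOR))
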