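"""Extraction of APA-style NHST results from normalized article text.

An in-text APA result carries three elements — test statistic, degrees of
freedom (except Z-tests), and a p-value claim — e.g. ``t(28) = 0.32,
p = .751``.  Eight test families are recognized: t, F, chi-square, Z,
correlation r, and the meta-analytic heterogeneity family (omnibus Q,
Q-between, Q-within).  A statistic without an accompanying p-value claim is
not a result; near-misses are skipped but tallied for diagnostics.

Matching is case-insensitive and tolerant of optional spaces around
operators, parentheses, and commas.  Free-floating degrees of freedom
("Q=35.72, 17 d.f.") are non-APA and deliberately not matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Union

from .ingest import RawDocument

__all__ = [
    "TestFamily",
    "ReportedNumber",
    "NhstResult",
    "NS",
    "extract_results",
    "detect_one_tailed_context",
    "format_result",
]


class TestFamily(str, Enum):
    __test__ = False  # statistical test families, not a test-runner fixture

    t = "t"
    F = "F"
    chi2 = "chi2"
    Z = "Z"
    r = "r"
    Q = "Q"
    Q_between = "Q_between"
    Q_within = "Q_within"


#: Families whose reference distribution is two-sided (eligible for the
#: one-tailed rescue); the upper-tail families F/chi2/Q have no two-sided
#: convention to halve.
TWO_SIDED_FAMILIES = frozenset({TestFamily.t, TestFamily.Z, TestFamily.r})

#: Families referred to a chi-square upper tail.
CHI_SQUARE_FAMILIES = frozenset(
    {TestFamily.chi2, TestFamily.Q, TestFamily.Q_between, TestFamily.Q_within}
)


class _NsSentinel:
    """Marker for a p-value reported only as 'ns' (not significant)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NS"


NS = _NsSentinel()


@dataclass(frozen=True)
class ReportedNumber:
    """A printed numeric claim: value, comparison operator, printed precision.

    ``decimals`` is the count of digits after the decimal point as printed;
    together with ``value`` and ``op`` the printed string is reconstructible.
    """

    value: float
    op: str = "="
    decimals: int = 2

    def __post_init__(self):
        if self.op not in ("=", "<", ">"):
            raise ValueError(f"invalid comparison operator {self.op!r}")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")


@dataclass(frozen=True)
class NhstResult:
    """One extracted in-text NHST result.

    Z results have no degrees of freedom; F results carry both ``df1`` and
    ``df2``; t, chi2, r and the Q family carry ``df1`` only.  ``n`` is the
    sample size when printed inside the chi-square parenthetical
    (``chi2(5, N = 36)``).  ``p_reported`` is either a :class:`ReportedNumber`
    or the :data:`NS` sentinel.
    """

    family: TestFamily
    statistic: ReportedNumber
    p_reported: Union[ReportedNumber, _NsSentinel]
    df1: Optional[float] = None
    df2: Optional[float] = None
    n: Optional[int] = None
    raw_span: str = ""
    offset: int = -1

    @property
    def is_ns(self) -> bool:
        return isinstance(self.p_reported, _NsSentinel)


# --------------------------------------------------------------------------
# Grammar
# --------------------------------------------------------------------------

_NUM = r"\d+(?:\.\d+)?"            # unsigned decimal (df, n)
_STAT = r"-?(?:\d+\.\d+|\.\d+|\d+)"  # signed statistic; no thousands separators
_PVAL = r"(?:\d+\.\d+|\.\d+|\d+)"

# Heads must not continue a word ("bidirectional" never yields "directional";
# "Hz = 50" never yields a Z-test).
_B = r"(?<![A-Za-z0-9_])"

_P_CLAIM = (
    r"\s*,\s*(?:p\s*(?P<p_op>[=<>])\s*(?P<p_val>" + _PVAL + r")"
    r"|(?P<ns>ns|n\.s\.?))(?![A-Za-z0-9])"
)

_FAMILY_PATTERNS = [
    # Q-between / Q-within before omnibus Q so "QB(2)" is not read as Q.
    (
        TestFamily.Q_between,
        _B + r"Q\s*[-_]?\s*(?:between|b)_?\s*\(\s*(?P<qb_df>" + _NUM + r")\s*\)"
        r"\s*(?P<qb_op>[=<>])\s*(?P<qb_val>" + _STAT + r")",
    ),
    (
        TestFamily.Q_within,
        _B + r"Q\s*[-_]?\s*(?:within|w)_?\s*\(\s*(?P<qw_df>" + _NUM + r")\s*\)"
        r"\s*(?P<qw_op>[=<>])\s*(?P<qw_val>" + _STAT + r")",
    ),
    (
        TestFamily.Q,
        _B + r"Q\s*\(\s*(?P<q_df>" + _NUM + r")\s*\)"
        r"\s*(?P<q_op>[=<>])\s*(?P<q_val>" + _STAT + r")",
    ),
    (
        TestFamily.chi2,
        _B + r"(?:χ2|chi2|chi[- ]?squared?|x2)\s*\(\s*(?P<c_df>" + _NUM + r")"
        r"\s*(?:,\s*n\s*=\s*(?P<c_n>\d+)\s*)?\)"
        r"\s*(?P<c_op>[=<>])\s*(?P<c_val>" + _STAT + r")",
    ),
    (
        TestFamily.F,
        _B + r"F\s*\(\s*(?P<f_df1>" + _NUM + r")\s*,\s*(?P<f_df2>" + _NUM + r")\s*\)"
        r"\s*(?P<f_op>[=<>])\s*(?P<f_val>" + _STAT + r")",
    ),
    (
        TestFamily.t,
        _B + r"t\s*\(\s*(?P<t_df>" + _NUM + r")\s*\)"
        r"\s*(?P<t_op>[=<>])\s*(?P<t_val>" + _STAT + r")",
    ),
    (
        TestFamily.r,
        _B + r"r\s*\(\s*(?P<r_df>" + _NUM + r")\s*\)"
        r"\s*(?P<r_op>[=<>])\s*(?P<r_val>" + _STAT + r")",
    ),
    (
        TestFamily.Z,
        _B + r"z\s*(?P<z_op>[=<>])\s*(?P<z_val>" + _STAT + r")",
    ),
]

_PREFIX = {
    TestFamily.Q_between: "qb",
    TestFamily.Q_within: "qw",
    TestFamily.Q: "q",
    TestFamily.chi2: "c",
    TestFamily.F: "f",
    TestFamily.t: "t",
    TestFamily.r: "r",
    TestFamily.Z: "z",
}

_RESULT_RE = re.compile(
    "(?:" + "|".join(pat for _, pat in _FAMILY_PATTERNS) + ")" + _P_CLAIM,
    re.IGNORECASE,
)

# A statistic claim with no p-value attached: counted as a near-miss, never
# extracted (the APA triple requires all three elements or statistic + ns).
_NEAR_MISS_RE = re.compile(
    "(?:" + "|".join(pat for _, pat in _FAMILY_PATTERNS) + ")",
    re.IGNORECASE,
)

_ONE_TAILED_RE = re.compile(
    r"\b(?:one[ -]tailed|one[ -]sided|directional)\b", re.IGNORECASE
)


def _decimals_of(printed: str) -> int:
    if "." in printed:
        return len(printed.split(".", 1)[1])
    return 0


def _match_to_result(m: re.Match) -> Optional[NhstResult]:
    family = next(
        fam for fam, _ in _FAMILY_PATTERNS if m.group(f"{_PREFIX[fam]}_val")
    )
    pre = _PREFIX[family]
    stat_str = m.group(f"{pre}_val")
    statistic = ReportedNumber(
        value=float(stat_str), op=m.group(f"{pre}_op"), decimals=_decimals_of(stat_str)
    )

    df1 = df2 = None
    n = None
    if family is TestFamily.F:
        df1 = float(m.group("f_df1"))
        df2 = float(m.group("f_df2"))
    elif family is not TestFamily.Z:
        df1 = float(m.group(f"{pre}_df"))
        if family is TestFamily.chi2 and m.group("c_n"):
            n = int(m.group("c_n"))

    if m.group("ns") is not None:
        p_reported: Union[ReportedNumber, _NsSentinel] = NS
    else:
        p_str = m.group("p_val")
        p_reported = ReportedNumber(
            value=float(p_str), op=m.group("p_op"), decimals=_decimals_of(p_str)
        )
        if not 0.0 <= p_reported.value <= 1.0:
            return None  # not a probability; near-miss

    if family is TestFamily.r and abs(statistic.value) > 1.0:
        return None  # correlations live in [-1, 1]; near-miss

    return NhstResult(
        family=family,
        statistic=statistic,
        p_reported=p_reported,
        df1=df1,
        df2=df2,
        n=n,
        raw_span=m.group(0),
        offset=m.start(),
    )


def extract_results(
    doc: RawDocument, diagnostics: Optional[Dict[str, int]] = None
) -> List[NhstResult]:
    """Find all APA-style NHST results in a document, in document order.

    Matches are maximal and non-overlapping.  Near-matches that fail a type
    invariant (an r outside [-1, 1], a p outside [0, 1]) or that lack the
    p-value element are skipped; when a ``diagnostics`` dict is supplied the
    counts land under ``"near_misses"`` and ``"invalid_values"``.
    """
    results: List[NhstResult] = []
    invalid = 0
    spans: List[tuple] = []
    for m in _RESULT_RE.finditer(doc.text):
        res = _match_to_result(m)
        if res is None:
            invalid += 1
            continue
        results.append(res)
        spans.append((m.start(), m.end()))

    if diagnostics is not None:
        total_stat_claims = 0
        for m in _NEAR_MISS_RE.finditer(doc.text):
            total_stat_claims += 1
        diagnostics["near_misses"] = (
            total_stat_claims - len(results) - invalid + diagnostics.get("near_misses", 0)
        )
        diagnostics["invalid_values"] = invalid + diagnostics.get("invalid_values", 0)
    return results


def detect_one_tailed_context(doc: RawDocument) -> bool:
    """True iff the article mentions one-tailed / one-sided / directional.

    Whole-word match: "bidirectional" does not count.
    """
    return _ONE_TAILED_RE.search(doc.text) is not None


# --------------------------------------------------------------------------
# Canonical serialization (round-trip partner of extract_results)
# --------------------------------------------------------------------------

_FAMILY_LABEL = {
    TestFamily.t: "t",
    TestFamily.F: "F",
    TestFamily.chi2: "chi2",
    TestFamily.Z: "Z",
    TestFamily.r: "r",
    TestFamily.Q: "Q",
    TestFamily.Q_between: "QB",
    TestFamily.Q_within: "QW",
}


def _fmt_df(df: float) -> str:
    return str(int(df)) if float(df).is_integer() else str(df)


def _fmt_number(num: ReportedNumber, leading_zero: bool = True) -> str:
    s = f"{num.value:.{num.decimals}f}"
    if not leading_zero:
        if s.startswith("0."):
            s = s[1:]
        elif s.startswith("-0."):
            s = "-" + s[2:]
    return s


def format_result(result: NhstResult) -> str:
    """Serialize a result in canonical APA form.

    P-values are printed without a leading zero (``p = .03``); ``ns`` stands
    in for a nonsignificance-only claim.  ``extract_results`` applied to the
    output reconstructs the semantic fields.
    """
    fam = result.family
    if fam is TestFamily.Z:
        if result.df1 is not None or result.df2 is not None:
            raise ValueError("Z results carry no degrees of freedom")
        head = _FAMILY_LABEL[fam]
    elif fam is TestFamily.F:
        if result.df1 is None or result.df2 is None:
            raise ValueError("F results need both df1 and df2")
        head = f"F({_fmt_df(result.df1)}, {_fmt_df(result.df2)})"
    else:
        if result.df1 is None or result.df2 is not None:
            raise ValueError(f"{fam.value} results need df1 only")
        if fam is TestFamily.chi2 and result.n is not None:
            head = f"chi2({_fmt_df(result.df1)}, n = {result.n})"
        else:
            head = f"{_FAMILY_LABEL[fam]}({_fmt_df(result.df1)})"
    if fam is TestFamily.r and abs(result.statistic.value) > 1.0:
        raise ValueError("correlation statistic outside [-1, 1]")

    stat = f"{head} {result.statistic.op} {_fmt_number(result.statistic)}"
    if result.is_ns:
        return f"{stat}, ns"
    p = result.p_reported
    if not 0.0 <= p.value <= 1.0:
        raise ValueError("reported p outside [0, 1]")
    return f"{stat}, p {p.op} {_fmt_number(p, leading_zero=False)}"
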