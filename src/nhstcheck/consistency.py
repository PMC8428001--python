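"""Classification of reported p-value claims against recomputed p-values.

A result is *consistent* when the printed p-value claim is compatible with
some p-value in the band induced by correct rounding of the printed
statistic; *inconsistent* when it is not; and *grossly inconsistent* when,
additionally, the statistical conclusion flips — the claim says significant
at alpha while the recomputed p-value says not, or vice versa.

Nonsignificance-only claims ("ns") are judged against the point-recomputed
p-value: the claim holds iff the recomputed p exceeds alpha.  "p = .000" is
an APA-style violation and is never satisfiable (the correct print is
"p < .001"); it is flagged inconsistent on its own, gross only when the
conclusion also flips.

When an article signals directional testing ("one-tailed", "one-sided",
"directional"), a failing claim on a two-sided family (t, Z, r) is re-tested
against the halved p-value band; success counts as a correctly reported
one-sided test (the one-tailed rescue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .extract import TWO_SIDED_FAMILIES, NhstResult, ReportedNumber
from .pvalues import PInterval

__all__ = ["CheckConfig", "Verdict", "classify", "CONSISTENT", "INCONSISTENT", "GROSS"]

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
GROSS = "gross"


@dataclass(frozen=True)
class CheckConfig:
    """Tunable checking behaviour.

    ``alpha`` — the significance level the conclusion is judged at (.05
    by default).  ``one_tailed_detection`` — whether the one-tailed rescue
    is attempted at all.  ``zero_p_always_inconsistent`` — whether
    "p = .000" is unconditionally a reporting violation.
    """

    alpha: float = 0.05
    one_tailed_detection: bool = True
    zero_p_always_inconsistent: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Verdict:
    result: NhstResult
    p_interval: PInterval
    consistency: str  # consistent | inconsistent | gross
    one_tailed_applied: bool
    reported_significant: Optional[bool]  # None = indeterminate (e.g. "p < .10")
    recomputed_significant: bool
    reason: str


def _is_zero_p_claim(p: Union[ReportedNumber, object]) -> bool:
    return isinstance(p, ReportedNumber) and p.op == "=" and p.value == 0.0


def _claim_satisfied(
    result: NhstResult, pint: PInterval, config: CheckConfig
) -> bool:
    """Does any p-value compatible with the printed statistic honor the claim?"""
    if result.is_ns:
        return pint.p_point > config.alpha
    p = result.p_reported
    if p.op == "=":
        if _is_zero_p_claim(p) and config.zero_p_always_inconsistent:
            return False
        # Half-up rounding: p* prints as `value` iff value-h <= p* < value+h.
        half = 0.5 * 10.0 ** (-p.decimals)
        return pint.p_lo < p.value + half and pint.p_hi >= p.value - half
    if p.op == "<":
        return pint.p_lo < p.value
    return pint.p_hi > p.value  # op ">"


def _reported_significance(
    result: NhstResult, alpha: float
) -> Optional[bool]:
    """Significance asserted by the printed claim; None when indeterminate.

    Printed "p = v": significant iff v < alpha (strict; v exactly alpha
    counts nonsignificant).  "p < v" asserts significance only when the
    bound is at or below alpha; "p > v" asserts nonsignificance only when
    the bound is at or above alpha.  "ns" asserts nonsignificance.
    """
    if result.is_ns:
        return False
    p = result.p_reported
    if p.op == "=":
        return p.value < alpha
    if p.op == "<":
        return True if p.value <= alpha else None
    return False if p.value >= alpha else None  # op ">"


def classify(
    result: NhstResult,
    pint: PInterval,
    one_tailed_context: bool,
    config: CheckConfig = CheckConfig(),
) -> Verdict:
    """Compare the reported p-value claim with the recomputed band.

    Deterministic; the same inputs always give the same verdict.
    """
    recomputed_significant = pint.p_point < config.alpha
    satisfied = _claim_satisfied(result, pint, config)
    one_tailed_applied = False

    if (
        not satisfied
        and config.one_tailed_detection
        and one_tailed_context
        and result.family in TWO_SIDED_FAMILIES
    ):
        if _claim_satisfied(result, pint.halved(), config):
            satisfied = True
            one_tailed_applied = True

    reported_significant = _reported_significance(result, config.alpha)

    if satisfied:
        return Verdict(
            result=result,
            p_interval=pint,
            consistency=CONSISTENT,
            one_tailed_applied=one_tailed_applied,
            reported_significant=reported_significant,
            recomputed_significant=recomputed_significant,
            reason="one_tailed_rescue" if one_tailed_applied else "ok",
        )

    gross = (
        reported_significant is not None
        and reported_significant != recomputed_significant
    )
    if gross:
        reason = "ns_but_significant" if result.is_ns else "sign_flip"
    elif _is_zero_p_claim(result.p_reported) and config.zero_p_always_inconsistent:
        reason = "zero_p_convention"
    else:
        reason = "rounding_mismatch"
    return Verdict(
        result=result,
        p_interval=pint,
        consistency=GROSS if gross else INCONSISTENT,
        one_tailed_applied=False,
        reported_significant=reported_significant,
        recomputed_significant=recomputed_significant,
        reason=reason,
    )
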