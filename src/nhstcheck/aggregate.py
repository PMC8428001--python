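"""Document- and corpus-level summaries of consistency checking.

Two prevalence definitions coexist in reporting-quality audits and are both
computed here:

* the **pooled** rate — all inconsistent results over all extracted results,
  across the corpus;
* the **averaged-within-article** rate — each article's own inconsistency
  percentage, averaged (with its SD) over articles that contain at least one
  result.  The two agree only when all articles report equally many results.

The bias analysis splits results by the significance their *printed* claim
asserts and compares error rates between the significant and nonsignificant
groups; a surplus on the significant side would indicate a systematic bias
toward reporting significant findings.  Both the gross-rate and the
any-inconsistency-rate splits are reported, since either can be the quantity
of interest.  Results whose printed claim is indeterminate at the chosen
alpha (e.g. "p < .10" at alpha .05) are excluded from both denominators.
"""

from __future__ import annotations

import statistics as pystats
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .consistency import CONSISTENT, GROSS, CheckConfig, Verdict, classify
from .extract import TestFamily, detect_one_tailed_context, extract_results
from .ingest import RawDocument
from .pvalues import p_interval

__all__ = ["DocumentReport", "CorpusSummary", "summarize_document", "summarize_corpus"]


@dataclass
class DocumentReport:
    """Per-article tally: every verdict plus counts by family.

    ``n_inconsistent`` includes gross inconsistencies; always
    ``n_gross <= n_inconsistent <= n_results``.
    """

    doc_id: str
    n_results: int
    n_inconsistent: int
    n_gross: int
    per_family_counts: Dict[TestFamily, Tuple[int, int, int]]
    one_tailed_context: bool
    verdicts: List[Verdict]
    year: Optional[int] = None


@dataclass
class CorpusSummary:
    n_docs: int
    n_docs_with_results: int
    pct_docs_with_results: Optional[float]
    total_results: int
    median_results_per_doc: Optional[float]  # over docs with >= 1 result
    n_docs_with_inconsistency: int
    pct_docs_with_inconsistency: Optional[float]
    n_docs_with_gross: int
    pct_docs_with_gross: Optional[float]
    result_level_pct_inconsistent: Optional[float]
    result_level_pct_gross: Optional[float]
    mean_within_doc_pct_inconsistent: Optional[float]
    sd_within_doc_pct_inconsistent: Optional[float]
    mean_within_doc_pct_gross: Optional[float]
    sd_within_doc_pct_gross: Optional[float]
    per_family_table: List[dict] = field(default_factory=list)
    bias_sig_rate: Optional[float] = None          # gross among reported-significant
    bias_nonsig_rate: Optional[float] = None       # gross among reported-nonsignificant
    bias_sig_rate_inconsistent: Optional[float] = None
    bias_nonsig_rate_inconsistent: Optional[float] = None
    per_year_prevalence: Dict[int, Tuple[int, int, float]] = field(default_factory=dict)


def summarize_document(
    doc: RawDocument, config: CheckConfig = CheckConfig()
) -> DocumentReport:
    """Run the full check on one document: extract, recompute, classify."""
    one_tailed = detect_one_tailed_context(doc)
    verdicts: List[Verdict] = []
    for res in extract_results(doc):
        pint = p_interval(res.family, res.statistic, res.df1, res.df2)
        verdicts.append(classify(res, pint, one_tailed, config))

    per_family: Dict[TestFamily, Tuple[int, int, int]] = {}
    n_inc = n_gross = 0
    for v in verdicts:
        fam = v.result.family
        ext, inc, gro = per_family.get(fam, (0, 0, 0))
        bad = v.consistency != CONSISTENT
        is_gross = v.consistency == GROSS
        per_family[fam] = (ext + 1, inc + bad, gro + is_gross)
        n_inc += bad
        n_gross += is_gross

    return DocumentReport(
        doc_id=doc.doc_id,
        n_results=len(verdicts),
        n_inconsistent=n_inc,
        n_gross=n_gross,
        per_family_counts=per_family,
        one_tailed_context=one_tailed,
        verdicts=verdicts,
        year=doc.year,
    )


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def summarize_corpus(reports: List[DocumentReport]) -> CorpusSummary:
    """Aggregate document reports into corpus-level prevalence and bias rates.

    Permutation-invariant in document order.  Rates whose denominator is
    empty are reported as ``None`` rather than zero.
    """
    n_docs = len(reports)
    with_results = [r for r in reports if r.n_results > 0]
    total_results = sum(r.n_results for r in reports)
    total_inc = sum(r.n_inconsistent for r in reports)
    total_gross = sum(r.n_gross for r in reports)

    within_inc = [100.0 * r.n_inconsistent / r.n_results for r in with_results]
    within_gross = [100.0 * r.n_gross / r.n_results for r in with_results]

    # Per-family rows, ordered by extraction count (largest first) then name.
    fam_tot: Dict[TestFamily, List[int]] = {}
    for r in reports:
        for fam, (ext, inc, gro) in r.per_family_counts.items():
            acc = fam_tot.setdefault(fam, [0, 0, 0])
            acc[0] += ext
            acc[1] += inc
            acc[2] += gro
    per_family_table = [
        {
            "family": fam.value,
            "n_extracted": ext,
            "n_inconsistent": inc,
            "pct_inconsistent": _pct(inc, ext),
            "n_gross": gro,
            "pct_gross": _pct(gro, ext),
        }
        for fam, (ext, inc, gro) in sorted(
            fam_tot.items(), key=lambda kv: (-kv[1][0], kv[0].value)
        )
    ]

    # Bias split by reported significance (printed claim), both readings.
    sig_n = nonsig_n = 0
    sig_gross = nonsig_gross = 0
    sig_inc = nonsig_inc = 0
    for r in reports:
        for v in r.verdicts:
            if v.reported_significant is None:
                continue
            bad = v.consistency != CONSISTENT
            gross = v.consistency == GROSS
            if v.reported_significant:
                sig_n += 1
                sig_gross += gross
                sig_inc += bad
            else:
                nonsig_n += 1
                nonsig_gross += gross
                nonsig_inc += bad

    # Per-year prevalence of documents containing >= 1 result.
    per_year: Dict[int, Tuple[int, int, float]] = {}
    years = sorted({r.year for r in reports if r.year is not None})
    for y in years:
        docs_y = [r for r in reports if r.year == y]
        with_y = sum(1 for r in docs_y if r.n_results > 0)
        per_year[y] = (len(docs_y), with_y, with_y / len(docs_y))

    def _mean_sd(xs: List[float]) -> Tuple[Optional[float], Optional[float]]:
        if not xs:
            return None, None
        mean = pystats.fmean(xs)
        sd = pystats.stdev(xs) if len(xs) > 1 else 0.0
        return mean, sd

    mean_inc, sd_inc = _mean_sd(within_inc)
    mean_gro, sd_gro = _mean_sd(within_gross)

    return CorpusSummary(
        n_docs=n_docs,
        n_docs_with_results=len(with_results),
        pct_docs_with_results=_pct(len(with_results), n_docs),
        total_results=total_results,
        median_results_per_doc=(
            float(pystats.median([r.n_results for r in with_results]))
            if with_results
            else None
        ),
        n_docs_with_inconsistency=sum(1 for r in reports if r.n_inconsistent > 0),
        pct_docs_with_inconsistency=_pct(
            sum(1 for r in reports if r.n_inconsistent > 0), len(with_results)
        ),
        n_docs_with_gross=sum(1 for r in reports if r.n_gross > 0),
        pct_docs_with_gross=_pct(
            sum(1 for r in reports if r.n_gross > 0), len(with_results)
        ),
        result_level_pct_inconsistent=_pct(total_inc, total_results),
        result_level_pct_gross=_pct(total_gross, total_results),
        mean_within_doc_pct_inconsistent=mean_inc,
        sd_within_doc_pct_inconsistent=sd_inc,
        mean_within_doc_pct_gross=mean_gro,
        sd_within_doc_pct_gross=sd_gro,
        per_family_table=per_family_table,
        bias_sig_rate=_pct(sig_gross, sig_n),
        bias_nonsig_rate=_pct(nonsig_gross, nonsig_n),
        bias_sig_rate_inconsistent=_pct(sig_inc, sig_n),
        bias_nonsig_rate_inconsistent=_pct(nonsig_inc, nonsig_n),
        per_year_prevalence=per_year,
    )
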