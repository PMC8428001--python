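"""Seeded synthetic article corpus with planted APA-style results.

Generates plain-text (optionally HTML and DOCX) documents whose in-text
statistical results have known ground truth, for end-to-end testing of the
extract → recompute → classify pipeline without any real articles.

Planted error classes mirror the failure modes seen in real reporting
audits:

* ``none`` — the p-value is reported correctly (rounded from the recomputed
  value, or as "ns" / "p < .05" where appropriate);
* ``rounding_slip`` — the last digit of a correctly rounded p drifts by one
  (.411 printed instead of .410): inconsistent but not gross;
* ``typo_digit`` — a digit is swapped (.37 instead of .47): inconsistent,
  sometimes gross;
* ``significance_flip`` — the p is printed on the wrong side of alpha:
  always gross;
* ``zero_p`` — printed as "p = .000", an APA violation: always inconsistent.

Documents also embed *decoys* — realistically formatted statements that are
NOT APA style (free-floating degrees of freedom, CI-only reports) and must
not be extracted; they appear in the manifest as negatives.

Statistics are drawn so the recomputed p stays clear of a ±0.002 band
around alpha (stable ground truth under rounding) unless a flip is being
planted.  Every planted result is verified against the classifier at build
time; a draw that fails to land in its intended class is redrawn, with
bounded retries.
"""

from __future__ import annotations

import html as html_mod
import zipfile
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import CONSISTENT, GROSS, INCONSISTENT, CheckConfig, classify
from .extract import NS, NhstResult, ReportedNumber, TestFamily, format_result
from .pvalues import p_interval

__all__ = ["PlantSpec", "PlantedResult", "generate_corpus"]


# Family weights follow the mix observed in meta-analytic reporting: Z and
# the heterogeneity Q family dominate, correlations are rare.
_DEFAULT_FAMILY_MIX: Dict[TestFamily, float] = {
    TestFamily.Z: 0.32,
    TestFamily.F: 0.18,
    TestFamily.chi2: 0.14,
    TestFamily.Q: 0.11,
    TestFamily.Q_between: 0.11,
    TestFamily.t: 0.10,
    TestFamily.Q_within: 0.01,
    TestFamily.r: 0.03,
}

# Roughly one result in five carries some reporting defect, of which only a
# small fraction flips the significance conclusion — the prevalence profile
# of published meta-analyses.
_DEFAULT_ERROR_RATES: Dict[str, float] = {
    "none": 0.82,
    "rounding_slip": 0.08,
    "typo_digit": 0.05,
    "zero_p": 0.035,
    "significance_flip": 0.015,
}


@dataclass(frozen=True)
class PlantSpec:
    """Generation parameters for a synthetic corpus."""

    n_docs: int = 24
    results_per_doc: Union[int, Tuple[int, int]] = (1, 10)
    family_mix: Dict[TestFamily, float] = field(
        default_factory=lambda: dict(_DEFAULT_FAMILY_MIX)
    )
    error_rates: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ERROR_RATES)
    )
    one_tailed_doc_rate: float = 0.1
    decoy_doc_rate: float = 0.3
    alpha: float = 0.05
    seed: int = 0
    formats: Tuple[str, ...] = ("txt",)

    def __post_init__(self):
        total = sum(self.error_rates.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error_rates must sum to 1, got {total}")
        if any(w < 0 for w in self.family_mix.values()):
            raise ValueError("family weights must be non-negative")


@dataclass(frozen=True)
class PlantedResult:
    """Manifest row: one planted result (or decoy) with its ground truth."""

    doc_id: str
    offset: int
    family: Optional[str]
    df1: Optional[float]
    df2: Optional[float]
    statistic: Optional[float]
    p_claim: str
    planted_error: str
    true_verdict: str  # consistent | inconsistent | gross | negative | skipped


_DECOYS = [
    "The studies were significantly heterogeneous according to the Q statistic (Q=35.72, 17 d.f., p<.0001).",
    "The overall effect size mean is 0.48 with a 95 percent confidence interval that covers zero (-0.36, 1.31).",
    "Meta-analysis revealed a significant difference favouring the intervention (SMD -0.32, 95% CI -0.63 to -0.01).",
    "The pooled RES for night-only studies was 1.01 (n.s.), indicating no effect.",
]

_FILLERS = [
    "The random-effects model combined the eligible studies.",
    "Subgroup analyses were conducted by study design.",
    "Effect sizes were weighted by inverse variance.",
    "Sensitivity analyses excluded high risk-of-bias studies.",
    "Publication bias was assessed with funnel plots.",
    "The moderator analysis considered participant age.",
]

_LEADINS = [
    "The test of the average effect was",
    "Heterogeneity across studies was assessed,",
    "The moderator test revealed",
    "For this outcome the analysis showed",
    "The pooled comparison yielded",
]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _draw_statistic(
    rng: np.random.Generator,
    family: TestFamily,
    p_target: float,
    stat_decimals: int,
) -> Tuple[float, Optional[float], Optional[float], Optional[int]]:
    """Invert a target p into a (rounded) statistic and degrees of freedom."""
    n = None
    if family is TestFamily.Z:
        value, df1, df2 = stats.norm.isf(p_target / 2.0), None, None
    elif family is TestFamily.t:
        df1 = int(rng.integers(5, 200))
        value, df2 = stats.t.isf(p_target / 2.0, df1), None
    elif family is TestFamily.r:
        df1 = int(rng.integers(10, 100))
        tval = stats.t.isf(p_target / 2.0, df1)
        value, df2 = tval / np.sqrt(df1 + tval**2), None
    elif family is TestFamily.F:
        df1 = int(rng.integers(1, 10))
        df2 = int(rng.integers(10, 200))
        value = stats.f.isf(p_target, df1, df2)
    else:  # chi-square and the Q family
        df1 = int(rng.integers(1, 20))
        value, df2 = stats.chi2.isf(p_target, df1), None
        if family is TestFamily.chi2 and rng.random() < 0.5:
            n = int(rng.integers(df1 + 2, 500))
    return float(np.round(value, stat_decimals)), df1, df2, n


def _plant_one(
    rng: np.random.Generator,
    family: TestFamily,
    error: str,
    config: CheckConfig,
    one_tailed: bool,
    max_attempts: int = 200,
) -> Optional[Tuple[NhstResult, str]]:
    """Draw one result landing in the verdict class its error type implies.

    Returns (result, true_verdict) or None when no admissible draw was
    found within the retry budget.
    """
    alpha = config.alpha
    for _ in range(max_attempts):
        significant = bool(rng.random() < 0.5)
        if error == "zero_p":
            significant = True  # ".000" reporters had small p-values
        if significant:
            p_target = float(rng.uniform(0.0026, alpha - 0.003))
        else:
            p_target = float(rng.uniform(alpha + 0.003, 0.9))
        stat_decimals = 3 if error == "rounding_slip" else 2
        value, df1, df2, n = _draw_statistic(rng, family, p_target, stat_decimals)
        statistic = ReportedNumber(value=value, op="=", decimals=stat_decimals)
        try:
            pint = p_interval(family, statistic, df1, df2)
        except ValueError:
            continue
        p_point = pint.p_point
        if abs(p_point - alpha) < 0.002 or p_point < 0.0025 or p_point > 0.95:
            continue  # keep ground truth stable under rounding

        p_claim = _make_claim(rng, error, p_point, alpha)
        if p_claim is None:
            continue
        result = NhstResult(
            family=family, statistic=statistic, p_reported=p_claim,
            df1=df1, df2=df2, n=n,
        )
        verdict = classify(result, pint, one_tailed, config)
        if _verdict_admissible(error, verdict.consistency):
            return result, verdict.consistency
    return None


def _make_claim(
    rng: np.random.Generator, error: str, p_point: float, alpha: float
):
    """Construct the printed p-value claim for an error class."""
    if error == "none":
        style = rng.random()
        if style < 0.15 and p_point > alpha:
            return NS
        if style < 0.30 and p_point < alpha:
            return ReportedNumber(value=alpha, op="<", decimals=2)
        decimals = 3 if rng.random() < 0.5 else 2
        v = _round_half_up(p_point, decimals)
        if v <= 0.0:
            return ReportedNumber(value=0.001, op="<", decimals=3)
        return ReportedNumber(value=v, op="=", decimals=decimals)
    if error == "rounding_slip":
        v = _round_half_up(p_point, 3)
        # Slip away from the side p_point sits on, so the shifted rounding
        # cell cannot still cover the recomputed band.
        delta = -0.001 if p_point >= v else 0.001
        v2 = round(v + delta, 3)
        if not 0.001 <= v2 <= 0.999:
            return None
        return ReportedNumber(value=v2, op="=", decimals=3)
    if error == "typo_digit":
        v = _round_half_up(p_point, 2)
        digits = [int(c) for c in f"{v:.2f}".split(".")[1]]
        pos = int(rng.integers(0, 2))
        old = digits[pos]
        choices = [d for d in range(10) if d != old]
        digits[pos] = int(rng.choice(choices))
        v2 = digits[0] / 10 + digits[1] / 100
        if v2 <= 0.0 or v2 > 1.0 or abs(v2 - v) < 0.005:
            return None
        return ReportedNumber(value=round(v2, 2), op="=", decimals=2)
    if error == "significance_flip":
        if p_point < alpha:
            if rng.random() < 0.5:
                return NS
            return ReportedNumber(
                value=_round_half_up(float(rng.uniform(alpha + 0.03, 0.9)), 2),
                op="=", decimals=2,
            )
        return ReportedNumber(
            value=_round_half_up(float(rng.uniform(0.005, alpha - 0.01)), 2),
            op="=", decimals=2,
        )
    if error == "zero_p":
        return ReportedNumber(value=0.0, op="=", decimals=3)
    raise ValueError(f"unknown error class {error!r}")


def _verdict_admissible(error: str, consistency: str) -> bool:
    if error == "none":
        return consistency == CONSISTENT
    if error == "rounding_slip":
        return consistency == INCONSISTENT
    if error == "typo_digit":
        return consistency in (INCONSISTENT, GROSS)
    if error == "significance_flip":
        return consistency == GROSS
    if error == "zero_p":
        return consistency in (INCONSISTENT, GROSS)
    raise ValueError(error)


# --------------------------------------------------------------------------
# Document assembly and file writers
# --------------------------------------------------------------------------


def _write_html(path: Path, lines: List[str]) -> None:
    body = "\n".join(f"<p>{html_mod.escape(line)}</p>" for line in lines)
    path.write_text(
        f"<html><head><title>{path.stem}</title></head>\n<body>\n{body}\n</body></html>\n",
        encoding="utf-8",
    )


_DOCX_CONTENT_TYPES = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="http://schemas.openxmlformats.org/package/2006/content-types">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Override PartName="/word/document.xml" ContentType="application/vnd.openxmlformats-officedocument.wordprocessingml.document.main+xml"/>
</Types>
"""

_DOCX_RELS = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="word/document.xml"/>
</Relationships>
"""


def _write_docx(path: Path, lines: List[str]) -> None:
    paras = "".join(
        '<w:p><w:r><w:t xml:space="preserve">{}</w:t></w:r></w:p>'.format(
            html_mod.escape(line)
        )
        for line in lines
    )
    document = (
        '<?xml version="1.0" encoding="UTF-8" standalone="yes"?>'
        '<w:document xmlns:w="http://schemas.openxmlformats.org/wordprocessingml/2006/main">'
        f"<w:body>{paras}</w:body></w:document>"
    )
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("[Content_Types].xml", _DOCX_CONTENT_TYPES)
        zf.writestr("_rels/.rels", _DOCX_RELS)
        zf.writestr("word/document.xml", document)


def generate_corpus(
    spec: PlantSpec, out_dir: Union[str, Path]
) -> List[PlantedResult]:
    """Write a synthetic corpus to ``out_dir`` and return its manifest.

    Emits one file per document per requested format plus ``manifest.csv``
    and a ``years.csv`` sidecar (doc_id, year) for prevalence trends.  The
    same seed always produces byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    config = CheckConfig(alpha=spec.alpha)

    families = sorted(spec.family_mix, key=lambda f: f.value)
    weights = np.array([spec.family_mix[f] for f in families], dtype=float)
    weights = weights / weights.sum()
    error_classes = sorted(spec.error_rates)
    error_probs = np.array([spec.error_rates[e] for e in error_classes])

    manifest: List[PlantedResult] = []
    years: List[Tuple[str, int]] = []

    for i in range(spec.n_docs):
        doc_id = f"synth{i:04d}"
        years.append((doc_id, 2000 + int(rng.integers(0, 18))))
        one_tailed = bool(rng.random() < spec.one_tailed_doc_rate)
        if isinstance(spec.results_per_doc, int):
            n_results = spec.results_per_doc
        else:
            lo, hi = spec.results_per_doc
            n_results = int(rng.integers(lo, hi + 1))

        lines: List[str] = [f"Synthetic review {doc_id}.", ""]
        if one_tailed:
            lines.append("All significance tests reported here were one-tailed.")
        pending: List[Tuple[str, str, NhstResult]] = []  # sentence, truth, result
        for _ in range(n_results):
            family = families[int(rng.choice(len(families), p=weights))]
            error = error_classes[int(rng.choice(len(error_classes), p=error_probs))]
            planted = _plant_one(rng, family, error, config, one_tailed)
            if planted is None:
                manifest.append(
                    PlantedResult(
                        doc_id=doc_id, offset=-1, family=family.value,
                        df1=None, df2=None, statistic=None, p_claim="",
                        planted_error=error, true_verdict="skipped",
                    )
                )
                continue
            result, truth = planted
            leadin = _LEADINS[int(rng.integers(0, len(_LEADINS)))]
            pending.append((leadin, error, result))

        decoy = None
        if rng.random() < spec.decoy_doc_rate:
            decoy = _DECOYS[int(rng.integers(0, len(_DECOYS)))]

        # Assemble the text, recording each planted result's char offset.
        planted_rows: List[PlantedResult] = []
        for leadin, error, result in pending:
            filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
            lines.append(filler)
            prefix = f"{leadin} "
            serialized = format_result(result)
            offset = sum(len(line) + 1 for line in lines) + len(prefix)
            lines.append(f"{prefix}{serialized}.")
            pint = p_interval(result.family, result.statistic, result.df1, result.df2)
            truth = classify(result, pint, one_tailed, config).consistency
            planted_rows.append(
                PlantedResult(
                    doc_id=doc_id,
                    offset=offset,
                    family=result.family.value,
                    df1=result.df1,
                    df2=result.df2,
                    statistic=result.statistic.value,
                    p_claim=(
                        "ns"
                        if result.is_ns
                        else f"{result.p_reported.op} {result.p_reported.value:.{result.p_reported.decimals}f}"
                    ),
                    planted_error=error,
                    true_verdict=truth,
                )
            )
        if decoy is not None:
            offset = sum(len(line) + 1 for line in lines)
            lines.append(decoy)
            planted_rows.append(
                PlantedResult(
                    doc_id=doc_id, offset=offset, family=None, df1=None,
                    df2=None, statistic=None, p_claim=decoy,
                    planted_error="decoy", true_verdict="negative",
                )
            )
        lines.append("")
        lines.append("In conclusion, the synthesis is summarized above.")

        text = "\n".join(lines) + "\n"
        if "txt" in spec.formats:
            (out_dir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        if "html" in spec.formats:
            _write_html(out_dir / f"{doc_id}.html", lines)
        if "docx" in spec.formats:
            _write_docx(out_dir / f"{doc_id}.docx", lines)
        manifest.extend(planted_rows)

    pd.DataFrame([vars(r) for r in manifest]).to_csv(
        out_dir / "manifest.csv", index=False
    )
    pd.DataFrame(years, columns=["doc_id", "year"]).to_csv(
        out_dir / "years.csv", index=False
    )
    return manifest
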