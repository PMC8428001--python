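# Methods

## The consistency model

An APA-style NHST report is an over-determined triple (statistic, degrees of
freedom, p-value): any two determine the third. `nhstcheck` treats the
statistic and df as given and asks whether the printed p-value claim is
*compatible* with them. The tool cannot tell which element is wrong — a
flagged result means the set of numbers is mutually inconsistent, nothing
more.

Reference distributions:

| family | df used | tail |
|---|---|---|
| t | df₁ | two-tailed, 2·P(T ≥ \|s\|) |
| Z | — | two-tailed, 2·(1 − Φ(\|s\|)) |
| r | df₁ = n − 2 | two-tailed via t = \|r\|·√(df/(1 − r²)) |
| F | df₁, df₂ | upper |
| χ², Q, Q-between, Q-within | df₁ | upper (χ² with printed df) |

The Q family is evaluated as a χ² upper tail because Cochran's Q is
asymptotically χ²(k − 1) under effect homogeneity, and the moderator-analysis
partition Q-between/Q-within inherits χ² reference distributions with their
own df. No continuity corrections are applied anywhere. |r| = 1 returns
p = 0 (degenerate but well-defined).

## Rounding-interval arithmetic

A statistic printed as `2.35` stands for any value in [2.345, 2.355) — the
upper bound half-open, since 2.355 would round half-up to 2.36. Because every
family's tail function is monotone in |statistic|, evaluating the two
endpoints bounds the attainable p-values; when the interval straddles zero
(a statistic printed `0.0`) the band's upper end is 1. A reported claim
`p = v` (printed with d decimals) is compatible when the band overlaps
v's own half-up rounding cell [v − 5·10⁻⁽ᵈ⁺¹⁾, v + 5·10⁻⁽ᵈ⁺¹⁾); `p < v` and
`p > v` are compatible when some band value satisfies them.

Two claims are judged by the *point* recomputed p-value rather than the
band:

* `ns` holds iff p_point > α. An "ns" print asserts a conclusion, not a
  number; judging it by the band would let a statistic that is significant
  as printed (e.g. Z = 1.96, p ≈ .0500) escape through the band's upper
  edge, which contradicts how such reports are audited in practice.
* `p = .000` is unconditionally a violation of APA style (the correct form
  is `p < .001`) when `zero_p_always_inconsistent` is on (default). It
  becomes gross only if the significance conclusion also flips.

## Severity

An incompatible claim is *gross* when the significance asserted by the print
differs from the recomputed conclusion (p_point vs α, strict inequality).
The printed side is read as: `p = v` significant iff v < α (printing exactly
`.05` asserts nonsignificance); `p < v` asserts significance only when
v ≤ α; `p > v` asserts nonsignificance only when v ≥ α; `ns` asserts
nonsignificance. Bounds that assert nothing at the chosen α (`p < .10` at
α = .05) are *indeterminate*: such failures are never gross, and these
results are excluded from the bias-analysis denominators.

## One-tailed rescue

If the article mentions "one-tailed", "one-sided", or "directional"
(whole-word, case-insensitive — "bidirectional" does not count), a failing
claim on a directional family (t, Z, r) is re-tested against the halved
band; success classifies the result as a correctly reported one-sided test.
The rescue never applies to F, χ², or Q tests: upper-tail statistics have no
two-sided convention to halve. It applies to both exact and bound claims.
Enabling the rescue can only move verdicts toward consistency.

## Extraction grammar

After normalization (NFKC, which also folds χ² → χ2; dash/space variants to
ASCII; emphasis asterisks dropped; blank runs collapsed within lines), the
grammar requires the full APA triple — or statistic plus `ns` — in
parenthetical-df form: `t(df)`, `F(df1, df2)`, `chi2(df)` / `χ2(df, n = N)`,
`r(df)`, bare `Z`, `Q(df)`, and `QB`/`Q_b`/`Q-between` (analogously
Q-within) with `(df)`. Matching is case-insensitive and tolerant of optional
spaces; heads must start a word, so `Hz = 50` is not a Z-test. Free-floating
df ("Q=35.72, 17 d.f.") is non-APA and deliberately unmatched, as are
statistics whose values violate type invariants (|r| > 1, p outside [0, 1]);
both are tallied as diagnostics rather than extracted. Statistical content
inside article tables is not specially filtered: table cells essentially
never match the full sentence grammar, which matches the in-text focus of
this kind of audit. Reference lists and supplements are scanned like any
other text.

Display convention: recomputed p-values are floor-truncated to three
decimals (`.0499…` prints as `.049`, not `.050`). Truncation is
presentation-only; every comparison uses full precision.

## Synthetic corpus

The generator emulates review articles whose in-text results have known
ground truth. Defaults reflect the reporting profile of published
meta-analyses: 24 documents of 1–10 results each (median ≈ 4); a family mix
dominated by Z (32%) and the heterogeneity family (Q 11%, Q-between 11%,
Q-within 1%) with F 18%, χ² 14%, t 10%, r 3%; and error rates
none .82, rounding-slip .08, digit-typo .05, zero-p .035,
significance-flip .015 — roughly one flawed result in five, of which a small
fraction is gross, matching observed inconsistency prevalence in this
literature. One document in ten declares one-tailed testing; three in ten
carry a decoy (a CI-only or free-floating-df statement that must not be
extracted).

Statistics are drawn by inverting a target p through the family's tail
function and rounding to the printed precision; draws whose recomputed p
lands within ±0.002 of α are rejected so ground truth is stable under
rounding (unless a significance flip is the goal). Each planted result is
verified against the classifier at generation time; a draw that does not
land in its intended verdict class is redrawn (bounded retries, then a
`skipped` manifest row — in practice never needed). Rounding slips print the
statistic at three decimals and perturb the third p decimal away from the
side the true p sits on, which provably cannot stay inside the rounding
band. A fixed seed yields byte-identical corpora.

What the generator does **not** emulate: PDF layout artifacts (hyphenation,
column reflow, glyph loss such as a dropped χ), tables, non-APA free-form
reporting beyond the fixed decoy list, and correlated errors within an
article. Passing the synthetic acceptance checks therefore demonstrates
correctness of the grammar, the recomputation, and the classifier on
well-formed in-text reporting — not robustness to degraded PDF text.

## Numerical choices

* Tail probabilities come from `scipy.stats` survival functions (extended
  precision in the far tail, no 1 − cdf cancellation).
* Truncation and half-up rounding go through `decimal.Decimal` on the
  shortest float repr, so binary representation noise cannot flip a printed
  digit.
* Claim-overlap comparisons use the half-open bounds exactly as derived; no
  epsilon fudging. The brute-force oracle used in tests scans 2001 grid
  points including both band endpoints, which is sufficient: any non-empty
  overlap of the band with a claim's rounding cell contains an endpoint or a
  full cell.
* Empty denominators yield absent (`None`/omitted) rates, never 0.

## Problem sizes

The acceptance run measures: the reference recomputations (7 rows,
milliseconds); end-to-end recall/agreement on 200 synthetic documents × 5
results = 1,000 planted results; classifier-vs-oracle agreement on 10,000
randomized results; distribution identities on ~1,500 grid points; and the
dual-rate arithmetic on hand-built corpora. The full suite plus acceptance
completes in well under a minute on one CPU.

## Known limitations

* PDF input is not read directly; articles must be converted to text, HTML,
  or DOCX first.
* The grammar requires APA-style parenthetical df; the large share of
  real-world results reported as point-estimate-plus-CI, or with free-form
  df, is invisible to it by design.
* A correctly reported test at a non-default α will be mis-flagged unless α
  is set accordingly (`--alpha`); the tool reads no α declarations from the
  article text.
* "Q/Z"-style ambiguous test labels are not special-cased.
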