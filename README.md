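# nhstcheck

Internal-consistency checking of null-hypothesis significance tests (NHST)
reported in-text in scientific articles — a "spellchecker for statistics"
aimed at meta-analyses and systematic reviews.

An APA-style result such as

```
t(28) = 0.32, p = .751
```

is redundant: the test statistic and degrees of freedom determine the
p-value. `nhstcheck` scans article text for such results, recomputes each
p-value from the printed statistic and df, and flags results whose reported
p-value cannot be right:

* **inconsistent** — the reported p-value does not match the recomputed one,
  even after allowing for correct rounding of the printed statistic;
* **grossly inconsistent** — additionally, the significance conclusion flips:
  the claim says p < α while the recomputed p is above α, or vice versa.

Eight test families are recognized: *t*, *F*, χ², *Z*, correlation *r*, and
the meta-analytic heterogeneity family — the omnibus Cochran *Q* test and its
moderator-analysis partition into *Q*-between and *Q*-within, all referred to
a χ² distribution with the printed df under the homogeneity null.

## The checking model

For a statistic printed as *s* with *d* decimals, the true value lies in the
rounding interval [s − 5·10⁻⁽ᵈ⁺¹⁾, s + 5·10⁻⁽ᵈ⁺¹⁾). Each family's tail
function maps this interval to a band of p-values [p_lo, p_hi]:

* two-tailed p = 2·P(T ≥ |s|) for *t*(df), *Z*, and *r* (via
  t = |r|·√(df/(1 − r²)), df = n − 2);
* upper-tail p = P(X ≥ s) for *F*(df₁, df₂) and for χ²/Q(df).

A claim `p = v` holds if some p\* in the band rounds (half-up, at the printed
precision) to *v*; `p < v` / `p > v` hold if some p\* in the band satisfies
them; `ns` holds iff the recomputed p exceeds α. `p = .000` violates APA
style (the correct print is `p < .001`) and is always flagged. If the article
mentions *one-tailed*, *one-sided*, or *directional* testing, a failing claim
on a two-sided family is re-tested against the halved p-value band (the
one-tailed rescue). Severity is judged by comparing the significance the
printed claim asserts with the recomputed p at α (default .05).

## Worked example

```python
>>> from nhstcheck import RawDocument, normalize_text, summarize_document
>>> text = ("The moderator test revealed QB(2) = 6.71, p = .03. "
...         "However, t(24) = 1.77, p = .03, and Z = 1.96, ns.")
>>> report = summarize_document(RawDocument("demo", normalize_text(text)))
>>> for v in report.verdicts:
...     print(f"{v.result.raw_span!r:34} p={v.p_interval.p_point:.3f} {v.consistency} ({v.reason})")
'QB(2) = 6.71, p = .03'            p=0.035 consistent (ok)
't(24) = 1.77, p = .03'            p=0.089 gross (sign_flip)
'Z = 1.96, ns'                     p=0.050 gross (ns_but_significant)
```

The Q-between claim is fine: χ²(2) ≥ 6.71 has p ≈ .0349, which rounds to .03.
The t-test's recomputed p ≈ .089 exceeds .05 while the claim asserts
significance — a gross inconsistency. The Z claim says "not significant" but
2·P(Z ≥ 1.96) ≈ .0500 is (just) below .05; at α = .01 the same claim would be
consistent (`CheckConfig(alpha=0.01)`).

From a shell:

```bash
nhstcheck check article.txt --format csv          # per-result records
nhstcheck corpus articles/ --out report           # corpus summary + records
nhstcheck simulate fixtures/ --n-docs 24 --seed 1 # synthetic test corpus
```

The corpus summary reports both prevalence definitions — the pooled
result-level rate and the averaged-within-article rate (mean ± SD of each
article's own percentage) — plus per-family rates and the significance-
direction bias split (error rates among results reported significant vs
nonsignificant).

## Synthetic corpora

`nhstcheck.generate_corpus` writes seeded plain-text/HTML/DOCX documents with
planted results of known ground truth (correct reports, last-digit rounding
slips, digit typos, significance flips, `p = .000` violations) alongside
decoy statements that are deliberately *not* APA style and must not be
extracted. The manifest records every planted result's true verdict, enabling
end-to-end recall and agreement measurement without any real articles.

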