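import numpy as np
import pytest

from nhstcheck import (
    NS,
    NhstResult,
    RawDocument,
    ReportedNumber,
    TestFamily,
    detect_one_tailed_context,
    extract_results,
    format_result,
    normalize_text,
)

from conftest import random_result


def doc(text: str) -> RawDocument:
    return RawDocument(doc_id="d", text=normalize_text(text))


def fields(r: NhstResult):
    return (r.family, r.df1, r.df2, r.n, r.statistic, r.p_reported)


class TestGrammar:
    @pytest.mark.parametrize(
        "text, family, df1, df2, stat, p",
        [
            ("t(28) = 0.32, p = .751", TestFamily.t, 28, None,
             ReportedNumber(0.32, "=", 2), ReportedNumber(0.751, "=", 3)),
            ("*t*(28) = 0.32, *p* = .751", TestFamily.t, 28, None,
             ReportedNumber(0.32, "=", 2), ReportedNumber(0.751, "=", 3)),
            ("(Q_B(2) = 6.71, p = .03)", TestFamily.Q_between, 2, None,
             ReportedNumber(6.71, "=", 2), ReportedNumber(0.03, "=", 2)),
            ("QB(2)=6.71,p=.03", TestFamily.Q_between, 2, None,
             ReportedNumber(6.71, "=", 2), ReportedNumber(0.03, "=", 2)),
            ("Q-between(2) = 6.71, p = .03", TestFamily.Q_between, 2, None,
             ReportedNumber(6.71, "=", 2), ReportedNumber(0.03, "=", 2)),
            ("QW(3) = 1.20, p > .05", TestFamily.Q_within, 3, None,
             ReportedNumber(1.2, "=", 2), ReportedNumber(0.05, ">", 2)),
            ("Q(17) = 35.72, p < .0001", TestFamily.Q, 17, None,
             ReportedNumber(35.72, "=", 2), ReportedNumber(0.0001, "<", 4)),
            ("F(2, 45) = 3.10, p = .055", TestFamily.F, 2, 45,
             ReportedNumber(3.1, "=", 2), ReportedNumber(0.055, "=", 3)),
            ("χ2(5, n = 36) = 11.05, p < .05", TestFamily.chi2, 5, None,
             ReportedNumber(11.05, "=", 2), ReportedNumber(0.05, "<", 2)),
            ("chi2(1) = 3.84, p = .05", TestFamily.chi2, 1, None,
             ReportedNumber(3.84, "=", 2), ReportedNumber(0.05, "=", 2)),
            ("chi-square(4) = 9.49, p = .05", TestFamily.chi2, 4, None,
             ReportedNumber(9.49, "=", 2), ReportedNumber(0.05, "=", 2)),
            ("r(40) = -.31, p = .04", TestFamily.r, 40, None,
             ReportedNumber(-0.31, "=", 2), ReportedNumber(0.04, "=", 2)),
            ("Z = 1.96, ns", TestFamily.Z, None, None,
             ReportedNumber(1.96, "=", 2), NS),
            ("z = -2.10 , p = 0.036", TestFamily.Z, None, None,
             ReportedNumber(-2.1, "=", 2), ReportedNumber(0.036, "=", 3)),
            ("t ( 24 ) = 1.77 , p = .03", TestFamily.t, 24, None,
             ReportedNumber(1.77, "=", 2), ReportedNumber(0.03, "=", 2)),
        ],
    )
    def test_single_result_families_and_fields(self, text, family, df1, df2, stat, p):
        results = extract_results(doc(text))
        assert len(results) == 1
        r = results[0]
        assert r.family is family
        assert r.df1 == df1
        assert r.df2 == df2
        assert r.statistic == stat
        assert r.p_reported == p

    @pytest.mark.parametrize(
        "text",
        [
            "",  # empty
            "(Q=35.72, 17 d.f., p<.0001)",  # free-floating df: not APA
            "t(28) = 0.32",  # statistic without a p-value claim
            "the mean was 4.5 (SD = 1.2)",
            "95% CI (-0.36, 1.31), p-value not shown",
            "r(40) = 1.31, p = .04",  # correlation outside [-1, 1]
            "t(28) = 0.32, p = 7.51",  # p outside [0, 1]
            "2 (5, n=36) = 11.05, p < .05",  # chi glyph lost: not recovered
            "the RES was 1.01 (n.s.)",  # no statistic triple
        ],
    )
    def test_non_apa_text_not_extracted(self, text):
        assert extract_results(doc(text)) == []

    def test_near_misses_counted_in_diagnostics(self):
        diag = {}
        extract_results(doc("t(28) = 0.32 and also t(10) = 2.0, p = .07"), diag)
        assert diag["near_misses"] == 1

    def test_multiple_results_in_document_order_non_overlapping(self):
        text = (
            "First, t(24) = 1.77, p = .03; later F(2, 45) = 3.10, p = .055, "
            "and finally Z = 1.96, ns."
        )
        results = extract_results(doc(text))
        assert [r.family for r in results] == [TestFamily.t, TestFamily.F, TestFamily.Z]
        assert results[0].offset < results[1].offset < results[2].offset
        for a, b in zip(results, results[1:]):
            assert a.offset + len(a.raw_span) <= b.offset

    def test_spacing_and_leading_zero_invariance(self):
        variants = [
            "t(28) = 0.32, p = .751",
            "t(28)=0.32,p=.751",
            "t (28) = 0.32, p = 0.751",
            "T(28) = 0.32, P = .751",
        ]
        parsed = [extract_results(doc(v))[0] for v in variants]
        assert all(r.family is TestFamily.t and r.df1 == 28 for r in parsed)
        assert all(r.statistic.value == 0.32 for r in parsed)
        assert all(r.p_reported.value == 0.751 for r in parsed)

    def test_qb_not_swallowed_by_omnibus_q(self):
        (r,) = extract_results(doc("Qb(1) = 5.38, ns"))
        assert r.family is TestFamily.Q_between

    def test_z_head_requires_word_boundary(self):
        assert extract_results(doc("the frequency in Hz = 50, p = .3")) == []


class TestOneTailedContext:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("we used a one-tailed test", True),
            ("a one tailed procedure", True),
            ("one-sided hypotheses were specified", True),
            ("the test was directional", True),
            ("A One-Sided test", True),
            ("the study was bidirectional", False),
            ("someone sided with the reviewers", False),
            ("", False),
        ],
    )
    def test_keyword_detection(self, text, expected):
        assert detect_one_tailed_context(doc(text)) is expected


class TestFormatResult:
    @pytest.mark.parametrize(
        "result, expected",
        [
            (NhstResult(TestFamily.t, ReportedNumber(1.77, "=", 2),
                        ReportedNumber(0.03, "=", 2), df1=24),
             "t(24) = 1.77, p = .03"),
            (NhstResult(TestFamily.F, ReportedNumber(3.10, "=", 2),
                        ReportedNumber(0.055, "=", 3), df1=2, df2=45),
             "F(2, 45) = 3.10, p = .055"),
            (NhstResult(TestFamily.Q_between, ReportedNumber(6.71, "=", 2),
                        ReportedNumber(0.03, "=", 2), df1=2),
             "QB(2) = 6.71, p = .03"),
            (NhstResult(TestFamily.Z, ReportedNumber(1.96, "=", 2), NS),
             "Z = 1.96, ns"),
            (NhstResult(TestFamily.chi2, ReportedNumber(11.05, "=", 2),
                        ReportedNumber(0.05, "<", 2), df1=5, n=36),
             "chi2(5, n = 36) = 11.05, p < .05"),
        ],
    )
    def test_canonical_serialization(self, result, expected):
        assert format_result(result) == expected

    @pytest.mark.parametrize(
        "bad",
        [
            NhstResult(TestFamily.Z, ReportedNumber(1.0), ReportedNumber(0.3), df1=5),
            NhstResult(TestFamily.F, ReportedNumber(1.0), ReportedNumber(0.3), df1=5),
            NhstResult(TestFamily.t, ReportedNumber(1.0), ReportedNumber(0.3)),
            NhstResult(TestFamily.r, ReportedNumber(1.5), ReportedNumber(0.3), df1=5),
            NhstResult(TestFamily.t, ReportedNumber(1.0), ReportedNumber(3.0), df1=5),
        ],
    )
    def test_invariant_violations_raise(self, bad):
        with pytest.raises(ValueError):
            format_result(bad)

    def test_round_trip_randomized(self, rng):
        """format_result then extract_results reconstructs the semantic fields."""
        for _ in range(1000):
            original = random_result(rng)
            text = f"Filler sentence. The analysis gave {format_result(original)}."
            results = extract_results(doc(text))
            assert len(results) == 1, format_result(original)
            assert fields(results[0])[:5] == (
                original.family,
                original.df1,
                original.df2,
                original.n,
                original.statistic,
            )
            assert results[0].p_reported == original.p_reported
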