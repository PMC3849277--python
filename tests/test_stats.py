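import math
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gofunsim import (
    binomial_pvalue,
    bonferroni,
    fuzzy_frequency,
    fuzzy_score,
    gospfit,
    gossfeat,
    hypergeom_pvalue,
    universal_ic,
)
from gofunsim.errors import (
    InputLimitError,
    MissingAnnotationError,
    NamespaceMismatchError,
    ParameterError,
)
from gofunsim.stats import agreement_level

from conftest import G, NS, make_random


def exact_hypergeom_tail(ell, n, m, N):
    """Rational upper tail by direct enumeration (independent oracle)."""
    total = Fraction(0)
    for k in range(ell, min(n, m) + 1):
        if n - k <= N - m:
            total += Fraction(comb(m, k) * comb(N - m, n - k), comb(N, n))
    return total


class TestFuzzyScore:
    def test_p1_g5_universal(self, graph, corpus, un_ic):
        a = fuzzy_score("universal", graph, un_ic, G["G5"], "P1", corpus, NS)
        assert a == pytest.approx(1 / 3, abs=1e-4)

    def test_direct_annotation_scores_one(self, graph, corpus, un_ic):
        assert fuzzy_score(
            "universal", graph, un_ic, G["G5"], "P2", corpus, NS
        ) == 1.0

    def test_delta_thresholds(self, graph, corpus, un_ic):
        a = fuzzy_score("universal", graph, un_ic, G["G5"], "P1", corpus, NS)
        assert a >= 0.3  # delta = 1 at moderate agreement
        assert a < 0.7  # delta = 0 at high agreement

    def test_unannotated_protein(self, graph, corpus, un_ic):
        with pytest.raises(MissingAnnotationError):
            fuzzy_score("universal", graph, un_ic, G["G5"], "P1", corpus,
                        "molecular_function")


class TestFuzzyFrequency:
    def test_toy_brute_force(self, graph, corpus, un_ic):
        proteins = corpus.proteins(NS)
        expected = sum(
            1
            for p in proteins
            if fuzzy_score("universal", graph, un_ic, G["G5"], p, corpus, NS)
            >= 0.3
        )
        ff = fuzzy_frequency(
            "universal", graph, un_ic, G["G5"], proteins, corpus, NS, 0.3
        )
        assert ff == expected == 5  # all five proteins score >= 1/3

    def test_high_agreement(self, graph, corpus, un_ic):
        ff = fuzzy_frequency(
            "universal", graph, un_ic, G["G5"], corpus.proteins(NS), corpus,
            NS, 0.7,
        )
        assert ff == 2  # only P2 and P5 carry G5 directly

    def test_root_zero_for_positive_c(self, graph, corpus, un_ic):
        ff = fuzzy_frequency(
            "universal", graph, un_ic, G["G1"], corpus.proteins(NS), corpus,
            NS, 0.3,
        )
        assert ff == 0

    def test_perfect_is_strictest_and_covers_direct(self, graph, corpus,
                                                    un_ic, usage):
        # c=1 counts direct-or-IC-equivalent annotation: it never exceeds the
        # moderate-agreement frequency and always covers direct annotators.
        # (It CAN exceed the closure count: a single child inherits its
        # parent's GO-universal IC, making their similarity exactly 1.)
        proteins = corpus.proteins(NS)
        for t in usage.counts:
            perfect = fuzzy_frequency(
                "universal", graph, un_ic, t, proteins, corpus, NS, 1.0
            )
            moderate = fuzzy_frequency(
                "universal", graph, un_ic, t, proteins, corpus, NS, 0.3
            )
            n_direct = sum(
                1 for p in proteins if t in corpus.direct(p, NS)
            )
            assert n_direct <= perfect <= moderate

    def test_perfect_exceeds_closure_count_for_equivalent_child(
        self, graph, corpus, un_ic, usage
    ):
        # G6 is G4's only child so IC_U(G6) == IC_U(G4) and sim(G6, G4) == 1;
        # P3 (annotated with G4) therefore counts for G6 at c=1 even though
        # G6 is not in P3's closure.
        ff = fuzzy_frequency(
            "universal", graph, un_ic, G["G6"], corpus.proteins(NS), corpus,
            NS, 1.0,
        )
        assert ff == 2 > usage.counts[G["G6"]] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_c(self, seed):
        graph, corpus = make_random(seed, n_terms=15, n_proteins=6)
        table = universal_ic(graph, NS)
        proteins = corpus.proteins(NS)
        terms = sorted(corpus.usage(NS).counts)[:6]
        for t in terms:
            ffs = [
                fuzzy_frequency(
                    "universal", graph, table, t, proteins, corpus, NS, c
                )
                for c in (0.1, 0.3, 0.7, 1.0)
            ]
            assert ffs == sorted(ffs, reverse=True)


class TestAgreementLevel:
    def test_presets(self):
        assert agreement_level("moderate") == 0.3
        assert agreement_level("high") == 0.7
        assert agreement_level("perfect") == 1.0

    def test_out_of_range(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                agreement_level(bad)


class TestHypergeomPvalue:
    def test_worked_example(self):
        assert hypergeom_pvalue(3, 5, 4, 10) == pytest.approx(66 / 252)

    def test_ell_zero(self):
        assert hypergeom_pvalue(0, 5, 4, 10) == 1.0

    def test_certain_event(self):
        assert hypergeom_pvalue(5, 5, 5, 5) == 1.0

    def test_inconsistent_counts(self):
        with pytest.raises(ParameterError):
            hypergeom_pvalue(6, 5, 4, 10)
        with pytest.raises(ParameterError):
            hypergeom_pvalue(1, 5, 11, 10)

    @given(
        st.integers(5, 40),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_rational_enumeration(self, N, data):
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        ell = data.draw(st.integers(0, n))
        exact = float(exact_hypergeom_tail(ell, n, m, N))
        assert hypergeom_pvalue(ell, n, m, N) == pytest.approx(
            exact, abs=1e-12, rel=1e-9
        )


class TestBinomialPvalue:
    def test_worked_example(self):
        assert binomial_pvalue(3, 5, 0.4) == pytest.approx(0.31744)

    def test_impossible_event(self):
        assert binomial_pvalue(1, 5, 0.0) == 0.0

    def test_ell_zero(self):
        assert binomial_pvalue(0, 5, 0.9) == 1.0

    def test_converges_to_hypergeometric(self):
        b = binomial_pvalue(3, 5, 0.4)
        h = hypergeom_pvalue(3, 5, 400_000, 1_000_000)
        assert abs(b - h) < 1e-3


class TestBonferroni:
    def test_table_values(self):
        # four-term query correction of the printed uncorrected p-values
        assert bonferroni([2.42e-14], 4)[0] == pytest.approx(9.68e-14)
        assert bonferroni([2.75e-14], 4)[0] == pytest.approx(1.10e-13)

    def test_cap_at_one(self):
        assert bonferroni([0.5], 4) == [1.0]

    def test_order_preserved(self):
        assert bonferroni([0.01, 0.001, 0.1], 3) == pytest.approx(
            [0.03, 0.003, 0.3]
        )

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            bonferroni([0.1], 0)
        with pytest.raises(ParameterError):
            bonferroni([0.1, 0.2], 1)


class TestGospfit:
    def test_toy_detected_set(self, graph, corpus, un_ic):
        rows = gospfit([G["G5"]], corpus, graph, un_ic, "universal", c=0.3)
        assert len(rows) == 1
        detected = {p for p, _ in rows[0].detected}
        # brute force: every protein scores >= 1/3 for G5 under GO-universal
        assert detected == {"P1", "P2", "P3", "P4", "P5"}
        assert rows[0].detected[0][1] == 1.0  # ranked by score descending

    def test_high_agreement_detected(self, graph, corpus, un_ic):
        rows = gospfit([G["G5"]], corpus, graph, un_ic, "universal", c=0.7)
        assert {p for p, _ in rows[0].detected} == {"P2", "P5"}

    def test_empty_detection_p_one(self, graph, corpus, un_ic):
        # root scores 0 for every protein, so nothing is detected
        rows = gospfit([G["G1"]], corpus, graph, un_ic, "universal", c=0.3)
        assert rows[0].detected == ()
        assert rows[0].p_value == 1.0

    def test_four_term_correction_factor(self, graph, corpus, un_ic):
        terms = [G["G3"], G["G4"], G["G5"], G["G6"]]
        rows = gospfit(terms, corpus, graph, un_ic, "universal", c=0.7)
        for r in rows:
            assert r.corrected_p == pytest.approx(min(1.0, r.p_value * 4))

    def test_limit_and_force(self, graph, corpus, un_ic):
        terms = [G["G5"]] * 21
        with pytest.raises(InputLimitError):
            gospfit(terms, corpus, graph, un_ic, "universal")
        rows = gospfit(terms, corpus, graph, un_ic, "universal", force=True)
        assert len(rows) == 21

    def test_mixed_namespace_error(self, corpus, un_ic):
        from gofunsim import parse_obo

        g2 = parse_obo(
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            "\n[Term]\nid: GO:0000009\nname: b\nnamespace: molecular_function\n"
        )
        with pytest.raises(NamespaceMismatchError):
            gospfit(["GO:0000001", "GO:0000009"], corpus, g2, None, "wang")


class TestGossfeat:
    def test_toy_perfect_agreement(self, graph, corpus, un_ic):
        rows = gossfeat(["P2", "P5"], corpus, graph, un_ic, "universal", c=1.0)
        by_term = {r.term: r for r in rows}
        # at c=1 only direct-equivalent annotation counts: G5 (P2, P5), G2 (P5)
        assert set(by_term) == {G["G5"], G["G2"]}
        g5 = by_term[G["G5"]]
        assert (g5.target_ff, g5.reference_ff) == (2, 2)
        # hand hypergeometric: P(X>=2 | N=5, m=2, n=2) = 1/10
        assert g5.p_value == pytest.approx(0.1)
        assert g5.corrected_p == pytest.approx(0.2)  # k = 2 tested terms
        g2 = by_term[G["G2"]]
        assert (g2.target_ff, g2.reference_ff) == (1, 1)
        assert g2.p_value == pytest.approx(0.4)
        assert rows[0].term == G["G5"]  # sorted by corrected p

    def test_target_equals_reference_p_one(self, graph, corpus, un_ic):
        rows = gossfeat(list(corpus.proteins(NS)), corpus, graph, un_ic,
                        "universal", c=0.3)
        assert rows
        for r in rows:
            assert r.p_value == pytest.approx(1.0)

    def test_single_test_correction_identity(self, graph, corpus, un_ic):
        rows = gossfeat(["P2", "P5"], corpus, graph, un_ic, "universal", c=1.0,
                        candidate_terms=[G["G5"]])
        assert len(rows) == 1
        assert rows[0].corrected_p == rows[0].p_value

    def test_empty_target_error(self, graph, corpus, un_ic):
        with pytest.raises(ParameterError):
            gossfeat([], corpus, graph, un_ic, "universal")

    def test_unknown_protein_strict_vs_lenient(self, graph, corpus, un_ic):
        from gofunsim.errors import UnknownIdentifierError

        with pytest.raises(UnknownIdentifierError):
            gossfeat(["P2", "nope"], corpus, graph, un_ic, "universal",
                     strict=True)
        rows = gossfeat(["P2", "nope"], corpus, graph, un_ic, "universal",
                        strict=False)
        assert rows

    def test_sorted_by_significance(self, graph, corpus, un_ic):
        rows = gossfeat(["P2", "P5"], corpus, graph, un_ic, "universal", c=0.3)
        ps = [r.corrected_p for r in rows]
        assert ps == sorted(ps)
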