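"""Over-representation analysis: exact tails, BH step-up, ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_hypergeom_tail
from netpharm.enrichment import (
    AnnotationLibrary,
    bh_adjust,
    fisher_enrich,
    hypergeom_upper_tail,
    read_gmt,
    top_k,
    write_gmt,
)
from netpharm.ingest import GeneSet
from netpharm.synthetic import gen_annotation_library


def make_universe(n):
    return [f"G{i:06d}" for i in range(1, n + 1)]


class TestGmtIO:
    def test_disjoint_terms_universe(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("term1\tdesc\tA\tB\tC\nterm2\tdesc\tD\tE\tF\n")
        lib = read_gmt(path)
        assert len(lib.universe) == 6
        assert lib.terms["term1"] == {"A", "B", "C"}

    def test_round_trip(self, tmp_path):
        universe = make_universe(60)
        lib = gen_annotation_library(universe, n_terms=8, term_size_range=(5, 15), seed=1)
        path = tmp_path / "lib.gmt"
        write_gmt(lib, path)
        back = read_gmt(path, name=lib.name, universe=set(universe))
        assert back.terms == lib.terms
        assert back.universe == lib.universe

    def test_short_line_rejected_with_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("term1\tdesc\tA\nterm2\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)

    def test_generated_library_bookkeeping(self):
        universe = make_universe(100)
        lib = gen_annotation_library(universe, n_terms=7, term_size_range=(10, 20), seed=2)
        assert len(lib.terms) == 7
        assert all(10 <= len(g) <= 20 for g in lib.terms.values())
        assert all(g <= lib.universe for g in lib.terms.values())


class TestFisher:
    def test_closed_form_half_universe(self):
        # N=10, K=5, n=5, k=5: only one of the C(10,5) draws hits all five
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-15)
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(
            oracle_hypergeom_tail(5, 5, 5, 10), abs=1e-15)

    def test_exhaustive_oracle_all_small_configs(self):
        for N in range(2, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                            oracle_hypergeom_tail(k, K, n, N), abs=1e-12), (N, K, n, k)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_upper_tail(0, 4, 5, 20) == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = make_universe(20)
        lib = gen_annotation_library(universe, n_terms=4, term_size_range=(3, 8), seed=3)
        terms = fisher_enrich(GeneSet("q", set(universe)), lib)
        assert all(t.p_value == pytest.approx(1.0) for t in terms)
        assert all(t.k == t.K for t in terms)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_upper_tail(k, 20, 30, 100) for k in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_genes_outside_universe_warned_and_dropped(self):
        lib = AnnotationLibrary(name="L", terms={"t": {"A", "B"}}, universe={"A", "B", "C"})
        with pytest.warns(UserWarning, match="outside"):
            terms = fisher_enrich(GeneSet("q", {"A", "ZZZ"}), lib)
        assert terms[0].n == 1

    def test_perfectly_matching_planted_term_ranks_first(self):
        universe = make_universe(50)
        query = set(universe[:8])
        terms = {"exact": set(query), "other1": set(universe[10:20]), "other2": set(universe[20:40])}
        lib = AnnotationLibrary(name="L", terms=terms, universe=set(universe))
        ranked = fisher_enrich(GeneSet("q", query), lib)
        assert ranked[0].term_id == "exact"
        assert ranked[0].p_value == min(t.p_value for t in ranked)

    def test_planted_terms_outrank_background(self):
        universe = make_universe(400)
        rng = np.random.default_rng(10)
        query = set(rng.choice(universe, size=60, replace=False))
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            lib = gen_annotation_library(universe, n_terms=10, term_size_range=(30, 50),
                                         planted_query=sorted(query), n_planted=2,
                                         enrichment_factor=6.0, seed=seed)
            ranked = fisher_enrich(GeneSet("q", query), lib)
            if all(t.term_id.startswith("PLANTED_") for t in ranked[:2]):
                wins += 1
        assert wins >= 0.95 * n_seeds


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_identical_and_single(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.7]) == pytest.approx([0.7])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, ps, rnd):
        order = list(range(len(ps)))
        rnd.shuffle(order)
        adjusted = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in order])
        for j, i in enumerate(order):
            assert shuffled[j] == pytest.approx(adjusted[i], abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTopK:
    def _terms(self):
        universe = make_universe(80)
        lib = gen_annotation_library(universe, n_terms=12, term_size_range=(5, 20), seed=6)
        return fisher_enrich(GeneSet("q", set(universe[:15])), lib)

    def test_truncation_and_order(self):
        terms = self._terms()
        top = top_k(terms, 5)
        assert len(top) == 5
        ps = [t.p_value for t in top]
        assert ps == sorted(ps)

    def test_k_larger_than_list(self):
        terms = self._terms()
        assert len(top_k(terms, 1000)) == len(terms)

    def test_tie_break_prefers_larger_overlap(self):
        from netpharm.enrichment import EnrichmentTerm

        a = EnrichmentTerm("tA", "L", k=2, K=10, n=5, N=100, p_value=0.5, fdr=0.5)
        b = EnrichmentTerm("tB", "L", k=4, K=10, n=5, N=100, p_value=0.5, fdr=0.5)
        assert top_k([a, b], 2)[0].term_id == "tB"

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_k([], 0)


class TestTypeICalibration:
    def test_null_rejection_rate_matches_exact_null(self):
        # at enrichment_factor=1 every term is a uniform draw, so k is
        # exactly hypergeometric; the empirical fraction of p<0.05 must
        # match the analytic null rejection probability (itself <= 0.05
        # because of discreteness) to binomial accuracy
        from scipy.stats import hypergeom

        universe = make_universe(500)
        rng = np.random.default_rng(99)
        query = set(rng.choice(universe, size=100, replace=False))
        n_seeds, n_terms = 100, 10
        lo, hi = 40, 60
        rejected = total = 0
        for seed in range(n_seeds):
            lib = gen_annotation_library(universe, n_terms=n_terms,
                                         term_size_range=(lo, hi),
                                         enrichment_factor=1.0, seed=seed)
            for term in fisher_enrich(GeneSet("q", query), lib):
                total += 1
                if term.p_value < 0.05:
                    rejected += 1
        N, n = len(universe), len(query)
        null_rates = []
        for K in range(lo, hi + 1):
            ks = np.arange(0, K + 1)
            pvals = hypergeom.sf(ks - 1, N, K, n)
            null_rates.append(float(hypergeom.pmf(ks, N, K, n)[pvals < 0.05].sum()))
        expected = float(np.mean(null_rates))
        se = (expected * (1 - expected) / total) ** 0.5
        assert expected <= 0.05
        assert abs(rejected / total - expected) < 3 * se + 1e-9
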