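"""Hypergeometric enrichment statistics.

The independent oracle used throughout is exhaustive enumeration: for a
universe of N genes with the pathway as the first n of them, every
C(N, K) significant-gene subset is generated and the fraction with at
least k pathway genes is the tail probability, in exact rationals.
"""

import math
from fractions import Fraction
from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from granora.stats import (
    EnrichmentQuery,
    ThresholdSpec,
    bh_adjust,
    bonferroni,
    enrich,
    enrichment_pvalue,
    hypergeom_pmf,
    lower_tail,
)


def enumerate_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Brute-force P(X >= k): count K-subsets touching the pathway >= k times."""
    pathway = set(range(n))
    hits = sum(1 for s in combinations(range(N), K) if len(pathway & set(s)) >= k)
    return Fraction(hits, math.comb(N, K))


class TestPmf:
    def test_degenerate_certainty(self):
        assert hypergeom_pmf(EnrichmentQuery(k=1, K=1, n=1, N=1)) == pytest.approx(1.0)

    def test_exact_rational_value(self):
        # C(2,0) C(4,3) / C(6,3) = 4/20
        assert hypergeom_pmf(EnrichmentQuery(k=0, K=2, n=3, N=6), exact=True) == Fraction(1, 5)
        assert hypergeom_pmf(EnrichmentQuery(k=0, K=2, n=3, N=6)) == pytest.approx(0.2)

    def test_pmf_normalizes(self):
        total = sum(
            hypergeom_pmf(EnrichmentQuery(k=k, K=5, n=7, N=20), exact=True)
            for k in range(0, 6)
        )
        assert total == 1

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(k=4, K=3, n=5, N=10)
        with pytest.raises(ValueError):
            EnrichmentQuery(k=1, K=2, n=11, N=10)


class TestTail:
    def test_single_pathway_fully_significant_in_1096_gene_background(self):
        # 3 significant genes all inside a 3-gene pathway, 1096 assigned genes
        p = enrichment_pvalue(EnrichmentQuery(k=3, K=3, n=3, N=1096))
        assert p == pytest.approx(4.6e-9, rel=0.02)

    def test_single_significant_gene_in_34_gene_pathway(self):
        p = enrichment_pvalue(EnrichmentQuery(k=1, K=1, n=34, N=1686))
        assert p == pytest.approx(2.0e-2, rel=0.02)

    def test_tail_matches_exhaustive_enumeration(self):
        # all C(6,2)=15 subsets; those touching the 3-gene pathway
        assert enumerate_tail(1, 2, 3, 6) == Fraction(4, 5)
        assert enrichment_pvalue(EnrichmentQuery(k=1, K=2, n=3, N=6)) == pytest.approx(0.8)

    def test_k_zero_is_exactly_one(self):
        assert enrichment_pvalue(EnrichmentQuery(k=0, K=5, n=7, N=100)) == 1.0

    def test_deep_tail_accuracy_against_exact_rational(self):
        # relative accuracy to >= 6 significant figures at p ~ 1e-41
        q = EnrichmentQuery(k=18, K=18, n=18, N=2000)
        exact = float(enrichment_pvalue(q, exact=True))
        assert exact < 1e-40
        assert enrichment_pvalue(q) == pytest.approx(exact, rel=1e-6)

    def test_agrees_with_scipy_survival_function(self):
        # independent library route: scipy parametrizes as (M, n_success, N_draws)
        for k, K, n, N in [(3, 10, 40, 500), (5, 5, 50, 1096), (2, 30, 7, 200)]:
            ours = enrichment_pvalue(EnrichmentQuery(k=k, K=K, n=n, N=N))
            theirs = scipy_hypergeom.sf(k - 1, N, K, n)
            assert ours == pytest.approx(theirs, rel=1e-10)

    def test_closed_form_when_all_significant_genes_in_pathway(self):
        # K = k: p reduces to the falling-factorial ratio n!/(n-k)! / (N!/(N-k)!)
        for k, n, N in [(3, 3, 1096), (5, 12, 1686), (7, 13, 1096)]:
            closed = math.perm(n, k) / math.perm(N, k)
            p = enrichment_pvalue(EnrichmentQuery(k=k, K=k, n=n, N=N))
            assert p == pytest.approx(closed, rel=1e-10)

    def test_lower_tail_complements_upper(self):
        q = EnrichmentQuery(k=3, K=10, n=20, N=100)
        assert lower_tail(q, exact=True) + enrichment_pvalue(q, exact=True) == 1


@given(
    st.integers(min_value=2, max_value=300).flatmap(
        lambda N: st.tuples(
            st.just(N),
            st.integers(min_value=1, max_value=N),  # K
            st.integers(min_value=1, max_value=N - 1),  # n1 < N
        )
    ),
    st.data(),
)
def test_property_pathway_size_monotonicity(params, data):
    """At fixed (N, K, k), a smaller pathway always gets a smaller p-value."""
    N, K, n1 = params
    n2 = data.draw(st.integers(min_value=n1 + 1, max_value=N), label="n2")
    k_lo = max(1, n1 + K - N + 1)  # keep the smaller pathway's tail below 1
    k_hi = min(n1, K)
    if k_lo > k_hi:
        return
    k = data.draw(st.integers(min_value=k_lo, max_value=k_hi), label="k")
    p1 = enrichment_pvalue(EnrichmentQuery(k=k, K=K, n=n1, N=N), exact=True)
    p2 = enrichment_pvalue(EnrichmentQuery(k=k, K=K, n=n2, N=N), exact=True)
    assert p1 < p2


@given(
    st.integers(min_value=2, max_value=200).flatmap(
        lambda N: st.tuples(
            st.just(N),
            st.integers(min_value=1, max_value=N),
            st.integers(min_value=1, max_value=N),
        )
    ),
    st.data(),
)
def test_property_tail_decreases_in_k(params, data):
    """P(X >= k) strictly decreases in k while k <= min(n, K).

    Strictness requires X >= k+1 not to be certain, so k+1 must exceed
    the support minimum n + K - N.
    """
    N, K, n = params
    kmax = min(n, K)
    k_lo = max(1, n + K - N)
    if k_lo > kmax - 1:
        return
    k = data.draw(st.integers(min_value=k_lo, max_value=kmax - 1), label="k")
    pa = enrichment_pvalue(EnrichmentQuery(k=k, K=K, n=n, N=N), exact=True)
    pb = enrichment_pvalue(EnrichmentQuery(k=k + 1, K=K, n=n, N=N), exact=True)
    assert pb < pa


def test_universe_monotonicity_in_fully_contained_regime():
    """With K = k fixed, enlarging the background strictly lowers p."""
    ps = [
        enrichment_pvalue(EnrichmentQuery(k=3, K=3, n=10, N=N))
        for N in (100, 500, 1096, 1686)
    ]
    assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCorrections:
    def test_bonferroni_reference_values(self):
        p = float(enrichment_pvalue(EnrichmentQuery(k=3, K=3, n=3, N=1096)))
        assert bonferroni(p, 354) == pytest.approx(1.6e-6, rel=0.02)
        assert bonferroni(2.0e-2, 119) == 1.0  # capped
        assert bonferroni(1.0, 5) == 1.0

    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.031]) == pytest.approx([0.031])

    def test_bh_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_rank1_penalty_equals_bonferroni(self):
        # the smallest of m p-values with all others large is multiplied by m
        ps = [1e-6, 0.5, 0.6, 0.7, 0.8]
        assert bh_adjust(ps)[0] == pytest.approx(1e-6 * 5)

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=30))
    def test_bh_dominates_raw_and_is_dominated_by_bonferroni(self, ps):
        adj = bh_adjust(ps)
        m = len(ps)
        for raw, a in zip(ps, adj):
            assert raw <= a + 1e-12
            assert a <= min(1.0, raw * m) + 1e-12

    def test_threshold_spec_cutoffs(self):
        assert ThresholdSpec(alpha=0.05, correction="none").raw_cutoff() == 0.05
        assert ThresholdSpec(alpha=0.05, correction="bonferroni", m=354).raw_cutoff() == (
            pytest.approx(0.05 / 354)
        )
        assert ThresholdSpec(
            alpha=0.05, correction="bh_rank1", m=354
        ).raw_cutoff() == pytest.approx(0.05 / 354)


class TestEnrich:
    def test_fully_perturbed_pathway_gets_minimum_p(self, tiny_db):
        results = enrich(tiny_db, {"g1", "g2", "g3"})
        assert results[0].pathway_id == "P1"
        assert results[0].query.k == 3

    def test_disjoint_pathway_has_p_one(self, tiny_db):
        results = enrich(tiny_db, {"g4", "g5"})
        by_id = {r.pathway_id: r for r in results}
        assert by_id["P1"].query.k == 0
        assert by_id["P1"].p_raw == 1.0

    def test_matches_enumeration_oracle_on_tiny_db(self, tiny_db):
        significant = {"g1", "g3"}
        results = {r.pathway_id: r for r in enrich(tiny_db, significant)}
        N = tiny_db.n_assigned  # 6
        for p in tiny_db.pathways:
            k = len(significant & p.genes)
            expected = enumerate_tail(k, len(significant), p.size, N)
            assert results[p.id].p_raw == pytest.approx(float(expected))

    def test_genes_outside_background_dropped_and_K_reduced(self, tiny_db, caplog):
        with caplog.at_level("WARNING"):
            results = enrich(tiny_db, {"g1", "not-a-gene"})
        assert results[0].query.K == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_no_overlap_with_background_is_error(self, tiny_db):
        with pytest.raises(ValueError):
            enrich(tiny_db, {"x", "y"})

    def test_corrected_ordering_invariant(self, tiny_db):
        for r in enrich(tiny_db, {"g1", "g2", "g4"}):
            assert r.p_raw <= r.p_bh + 1e-12 <= r.p_bonferroni + 1e-12
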