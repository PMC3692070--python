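"""Hypergeometric tail, multiplicity adjustment, term enrichment, annotation."""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import metanet as mn
from metanet.enrich import EnrichmentError


def subset_tail(k: int, K: int, n: int, N: int) -> float:
    """Independent oracle: enumerate all C(N, n) subsets and count those
    containing at least k of the K annotated items."""
    annotated = set(range(K))
    hits = sum(
        1 for s in combinations(range(N), n) if len(annotated & set(s)) >= k
    )
    total = sum(1 for _ in combinations(range(N), n))
    return hits / total


class TestHypergeomTail:
    def test_k_zero_is_certain(self):
        assert mn.hypergeom_tail(0, 4, 3, 10) == 1.0

    def test_fully_annotated_background(self):
        assert mn.hypergeom_tail(3, 10, 3, 10) == 1.0

    def test_spec_example_third(self):
        # frozen from the subset-enumeration oracle: 40 of the 120 3-subsets
        # of a 10-item background contain >= 2 of the 4 annotated items
        assert subset_tail(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-15)
        assert mn.hypergeom_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_subset_enumeration_small_grid(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert mn.hypergeom_tail(k, K, n, N) == pytest.approx(
                            subset_tail(k, K, n, N), rel=1e-10
                        )

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(1, 500))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert mn.hypergeom_tail(k, K, n, N) == pytest.approx(
                scipy.stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )

    def test_pmf_sums_to_one_and_tail_monotone(self):
        for N, K, n in [(10, 4, 3), (12, 6, 5), (7, 7, 2), (9, 0, 4)]:
            tails = [mn.hypergeom_tail(k, K, n, N) for k in range(min(n, K) + 1)]
            pmf = [t - t2 for t, t2 in zip(tails, tails[1:] + [0.0])]
            assert sum(pmf) == pytest.approx(1.0, rel=1e-12)
            assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    @pytest.mark.parametrize("k,K,n,N", [(3, 2, 5, 10), (1, 11, 3, 10), (1, 2, 11, 10)])
    def test_invalid_counts_rejected(self, k, K, n, N):
        with pytest.raises(EnrichmentError):
            mn.hypergeom_tail(k, K, n, N)


def bh_oracle(ps: list[float]) -> list[float]:
    """Direct step-up formula: p(i)*m/i with a cumulative minimum."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        out[i] = running
    return out


class TestAdjust:
    def test_bh_spec_example(self):
        assert mn.adjust_pvalues([0.01, 0.02, 0.03], "bh") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_value(self):
        assert mn.adjust_pvalues([0.2], "bonferroni") == [0.2]
        assert mn.adjust_pvalues([0.2], "bh") == [0.2]

    def test_empty(self):
        assert mn.adjust_pvalues([], "bh") == []

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            mn.adjust_pvalues([0.0, 0.5], "bh")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_bh_matches_step_up_oracle(self, ps):
        got = mn.adjust_pvalues(ps, "bh")
        want = bh_oracle(ps)
        assert got == pytest.approx(want, rel=1e-9)
        assert all(g >= p - 1e-12 for g, p in zip(got, ps))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        ps = list(rng.uniform(0.001, 1.0, size=12))
        perm = list(rng.permutation(12))
        direct = mn.adjust_pvalues(ps, "bh")
        permuted = mn.adjust_pvalues([ps[i] for i in perm], "bh")
        assert permuted == pytest.approx([direct[i] for i in perm])


class TestEnrichTerms:
    def test_fix1_deep_term(self, bundle):
        res = mn.enrich_terms({"g1", "g2"}, bundle.disease_hierarchy,
                              bundle.disease_annotations)
        by_term = {r.term_id: r for r in res}
        d1a = by_term["D1a"]
        assert (d1a.k, d1a.K, d1a.n, d1a.N) == (2, 2, 2, 4)
        assert d1a.p_raw == pytest.approx(1 / 6)
        assert res[0].term_id == "D1a"

    def test_whole_background_query_is_uninformative(self, bundle):
        res = mn.enrich_terms({"g1", "g2", "g3", "g4"}, bundle.disease_hierarchy,
                              bundle.disease_annotations)
        assert all(r.p_raw == pytest.approx(1.0) for r in res)

    def test_single_gene_ranks_its_leaf_first(self, bundle):
        res = mn.enrich_terms({"g4"}, bundle.disease_hierarchy,
                              bundle.disease_annotations)
        leaves = [r for r in res
                  if not bundle.disease_hierarchy.children(r.term_id)]
        assert leaves[0].term_id == "D2"

    def test_empty_effective_query_rejected(self, bundle):
        with pytest.raises(EnrichmentError):
            mn.enrich_terms({"g99"}, bundle.disease_hierarchy,
                            bundle.disease_annotations)

    def test_adjusted_never_below_raw(self, bundle):
        res = mn.enrich_terms({"g1", "g2"}, bundle.disease_hierarchy,
                              bundle.disease_annotations, include_unhit=True)
        assert all(r.p_adj >= r.p_raw - 1e-12 for r in res)

    def test_planted_term_recovered_across_seeds(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            b = mn.generate_fixture(
                mn.FixtureSpec(seed=seed, planted_term="DIS:0015", planted_fraction=0.8)
            )
            res = mn.enrich_terms(b.query, b.disease_hierarchy, b.disease_annotations)
            top = res[0].term_id
            ancestors = {t for path in
                         mn.paths_to_root(b.disease_hierarchy, "DIS:0015")
                         for t in path}
            hits += top in ancestors
        assert hits >= round(0.95 * n_seeds)


class TestAnnotateNodes:
    def test_gene_gets_its_direct_terms(self, bundle, drug_target_graph):
        mn.annotate_nodes(drug_target_graph, bundle.disease_hierarchy,
                          bundle.disease_annotations)
        assert drug_target_graph.nodes["g1"].properties["annotations"] == "D1a"
        assert drug_target_graph.nodes["g2"].properties["annotations"] == "D1a,D2"

    def test_cumulative_adds_ancestors(self, bundle, drug_target_graph):
        mn.annotate_nodes(drug_target_graph, bundle.disease_hierarchy,
                          bundle.disease_annotations, cumulative=True)
        assert drug_target_graph.nodes["g1"].properties["annotations"] == "D1,D1a,R"

    def test_drug_gets_therapy_terms(self, bundle, drug_target_graph):
        mn.annotate_nodes(drug_target_graph, bundle.therapy_hierarchy,
                          bundle.therapy_annotations)
        assert drug_target_graph.nodes["d2"].properties["annotations"] == "T1,T2"

    def test_remove_on_unannotated_node_is_noop(self, bundle, drug_target_graph):
        mn.annotate_nodes(drug_target_graph, bundle.disease_hierarchy,
                          bundle.disease_annotations, add=False)
        assert "annotations" not in drug_target_graph.nodes["g5"].properties

    def test_kind_mismatch_rejected(self, bundle, drug_target_graph):
        with pytest.raises(EnrichmentError):
            mn.annotate_nodes(drug_target_graph, bundle.therapy_hierarchy,
                              bundle.therapy_annotations, nodes=["g1"])
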