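"""Enrichment statistics: hypergeometric, GSEA, BH, consensus, MH meta."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inparkit.genesets import (
    EnrichmentRecord,
    GeneSetCollection,
    bh_qvalues,
    consensus_enriched,
    gsea_enrichment,
    gsea_running_sum,
    hypergeometric_enrichment,
    jaccard_overlap_map,
    mh_meta_or,
)


def _hyper_bruteforce(N, K, n, k):
    """Upper-tail hypergeometric p by full enumeration of overlaps."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometric:
    def test_exact_small_table(self):
        # N=10, n=4, K=5, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        uni = [f"g{i}" for i in range(10)]
        rec = hypergeometric_enrichment(uni[:4], uni[:5], uni)
        assert rec.p_hyper == pytest.approx(5 / 210)
        assert (rec.k, rec.K, rec.n, rec.N) == (4, 5, 4, 10)

    def test_balanced_table_odds_ratio_one(self):
        uni = [f"g{i}" for i in range(40)]
        # cells 10/10/10/10: sig = first 20, set = alternating halves
        sig = uni[:20]
        members = uni[:10] + uni[20:30]
        rec = hypergeometric_enrichment(sig, members, uni)
        assert rec.odds_ratio == pytest.approx(1.0)

    def test_zero_overlap_is_depletion(self):
        uni = [f"g{i}" for i in range(20)]
        rec = hypergeometric_enrichment(uni[:5], uni[5:12], uni)
        assert rec.odds_ratio < 1
        assert rec.p_hyper > 0.9

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], [], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(5, 30))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        uni = [f"g{i}" for i in range(N)]
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        members = list(rng.choice(uni, size=K, replace=False))
        sig = list(rng.choice(uni, size=n, replace=False))
        rec = hypergeometric_enrichment(sig, members, uni)
        assert rec.p_hyper == pytest.approx(_hyper_bruteforce(N, K, n, rec.k), rel=1e-9)


class TestGsea:
    def test_perfect_separation_reaches_one(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.arange(10, 0, -1, dtype=float)
        es = gsea_running_sum(genes, scores, set(genes[:3]), weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_hand_running_sum_interleaved(self):
        # 4 genes, set at ranks 1 and 3, weight 0: +1/2, 0, +1/2, 0
        genes = ["a", "b", "c", "d"]
        es = gsea_running_sum(genes, np.ones(4), {"a", "c"}, weight_exponent=0)
        assert es == pytest.approx(0.5)

    def test_reversed_ranking_negates_score_at_weight_zero(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        scores = np.sort(rng.standard_normal(40))[::-1]
        members = set(rng.choice(genes, size=8, replace=False))
        fwd = gsea_running_sum(genes, scores, members, weight_exponent=0)
        rev = gsea_running_sum(genes[::-1], scores[::-1], members, weight_exponent=0)
        assert rev == pytest.approx(-fwd)

    def test_signal_set_gets_small_permutation_p(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(100)]
        scores = np.sort(rng.standard_normal(100))[::-1] + 0.0
        ranked = pd.Series(scores, index=genes)
        es, p = gsea_enrichment(ranked, set(genes[:10]), n_perm=200, seed=0)
        assert es > 0.5
        # the p floor is 1/(same-signed permutations + 1), about 2/n_perm
        assert p <= 0.02

    def test_no_overlap_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            gsea_enrichment(ranked, {"zz"}, n_perm=10, seed=0)


class TestBH:
    def test_hand_stepup_flat(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_stepup_mixed(self):
        assert bh_qvalues([0.005, 0.05, 0.5]) == pytest.approx([0.015, 0.075, 0.5])

    def test_single_p_unchanged(self):
        assert bh_qvalues([0.3]) == pytest.approx([0.3])

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q = bh_qvalues(p)
        q_perm = bh_qvalues(p[perm])
        assert q[perm] == pytest.approx(q_perm)


class TestConsensus:
    def _rec(self, qh, qg):
        r = EnrichmentRecord(name="s", k=1, K=2, n=3, N=10, odds_ratio=1.0, p_hyper=0.1)
        r.q_hyper, r.q_gsea = qh, qg
        return r

    def test_requires_both_tests(self):
        assert consensus_enriched([self._rec(0.01, 0.30)], fdr=0.05) == []

    def test_boundary_is_inclusive(self):
        assert len(consensus_enriched([self._rec(0.05, 0.05)], fdr=0.05)) == 1

    def test_empty_input(self):
        assert consensus_enriched([], fdr=0.05) == []


class TestJaccard:
    def test_pairwise_values(self):
        coll = GeneSetCollection({"x": {"a", "b"}, "y": {"b", "c"}, "z": {"a", "b"}})
        g = jaccard_overlap_map(coll, min_jaccard=0.0)
        assert g["x"]["y"]["weight"] == pytest.approx(1 / 3)
        assert g["x"]["z"]["weight"] == pytest.approx(1.0)

    def test_disjoint_sets_never_linked(self):
        coll = GeneSetCollection({"x": {"a"}, "y": {"b"}})
        g = jaccard_overlap_map(coll, min_jaccard=0.0)
        assert g.number_of_edges() == 0

    def test_threshold_excludes_weak_overlap(self):
        coll = GeneSetCollection({"x": {"a", "b"}, "y": {"b", "c"}})
        g = jaccard_overlap_map(coll, min_jaccard=0.5)
        assert not g.has_edge("x", "y")


class TestMantelHaenszel:
    def test_identical_tables_preserve_or(self):
        t = np.array([[10, 20], [5, 40]])
        single_or = (10 * 40) / (20 * 5)
        out = mh_meta_or([t, t])
        assert out["or_pooled"] == pytest.approx(single_or)

    def test_reciprocal_tables_pool_to_null(self):
        t1 = np.array([[20, 10], [10, 20]])  # OR 4
        t2 = np.array([[10, 20], [20, 10]])  # OR 1/4
        out = mh_meta_or([t1, t2])
        assert out["or_pooled"] == pytest.approx(1.0)
        assert out["heterogeneous"]  # opposite effects trip the Woolf test

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            mh_meta_or([np.array([[1, 2], [3, 4]])])

    def test_zero_margin_table_excluded(self):
        good = np.array([[10, 20], [5, 40]])
        bad = np.array([[0, 0], [5, 40]])
        out = mh_meta_or([good, good, bad])
        assert out["or_pooled"] == pytest.approx((10 * 40) / (20 * 5))
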