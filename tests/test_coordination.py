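"""Correlation enrichment, Fisher-z differences, binomial excess, sign test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inparkit.coordination import (
    all_pairs,
    correlation_difference_table,
    correlation_enrichment,
    cross_pairs,
    dysregulation_summary,
    fisher_z_difference,
    round_half_up,
    sign_test_superiority,
)
from inparkit.synthdata import GwasConfig, PpiConfig, SyntheticConfig, generate_expression


def _block_matrix(n_genes=40, n_samples=30, block=8, rho=0.8, seed=0):
    """Homogeneous noise with one equicorrelated block of genes."""
    rng = np.random.default_rng(seed)
    c = np.eye(n_genes)
    c[:block, :block] = rho
    np.fill_diagonal(c, 1.0)
    x = np.linalg.cholesky(c) @ rng.standard_normal((n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(x, index=genes, columns=[f"s{j}" for j in range(n_samples)]), genes[:block]


class TestCorrelationEnrichment:
    def test_planted_block_recovered(self):
        mat, block = _block_matrix()
        res = correlation_enrichment(mat, set(block), n_perm=200, seed=1)
        assert res.mean_abs_rho_set > res.mean_abs_rho_null
        assert res.auc > 0.9
        assert res.p_perm <= 0.01

    def test_random_set_is_null(self):
        rng = np.random.default_rng(5)
        mat, _ = _block_matrix(rho=0.0, seed=5)
        random_set = set(rng.choice(mat.index, size=8, replace=False))
        res = correlation_enrichment(mat, random_set, n_perm=200, seed=6)
        assert abs(res.auc - 0.5) < 0.12
        assert res.p_perm > 0.05

    def test_response_target_ranks_associated_genes(self):
        rng = np.random.default_rng(7)
        mat, block = _block_matrix(rho=0.0, seed=7)
        response = mat.loc[block].mean(axis=0) + 0.3 * rng.standard_normal(mat.shape[1])
        response.name = "protein"
        res = correlation_enrichment(mat, set(block), target=response, n_perm=200, seed=8)
        assert res.target == "protein"
        assert res.mean_abs_rho_set > res.mean_abs_rho_null
        assert res.auc > 0.7
        assert res.p_perm <= 0.01

    def test_perfect_separation_auc_one(self):
        # two genes forming an exact linear pair vs an uncorrelated rest
        rng = np.random.default_rng(9)
        base = rng.standard_normal(20)
        mat = pd.DataFrame(
            np.vstack([base, 2 * base, rng.standard_normal((6, 20))]),
            index=[f"g{i}" for i in range(8)],
        )
        res = correlation_enrichment(mat, {"g0", "g1"}, n_perm=50, seed=0)
        assert res.auc == pytest.approx(1.0)

    def test_auc_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(11)
        mat, block = _block_matrix(n_genes=15, block=5, rho=0.5, seed=11)
        res = correlation_enrichment(mat, set(block), n_perm=20, seed=12)
        # independent oracle: count in-group vs null-group wins pair by pair
        from inparkit.coordination import _group_scores, _spearman_matrix

        corr = _spearman_matrix(mat.to_numpy())
        in_s, null_s = _group_scores(corr, np.asarray(mat.index.isin(block)))
        wins = sum((a > b) + 0.5 * (a == b) for a in in_s for b in null_s)
        assert res.auc == pytest.approx(wins / (len(in_s) * len(null_s)))


class TestFisherZ:
    def test_identical_arms_give_p_one(self):
        rng = np.random.default_rng(0)
        arm = pd.DataFrame(rng.standard_normal((2, 10)), index=["a", "b"])
        out = correlation_difference_table(arm, arm.copy(), [("a", "b")])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # rho 0.9 vs 0.0 at n=50 per arm: z ~ 7.13, p ~ 1e-12
        z, p = fisher_z_difference(0.9, 0.0, 50, 50)
        assert z == pytest.approx(7.1368, abs=1e-3)
        assert p == pytest.approx(9.55e-13, rel=0.01)

    def test_unit_correlation_clipped_not_infinite(self):
        z, p = fisher_z_difference(1.0, 0.0, 20, 20)
        assert np.isfinite(z) and 0.0 <= p <= 1.0

    def test_symmetric_in_arm_order(self):
        z1, p1 = fisher_z_difference(0.7, 0.2, 30, 40)
        z2, p2 = fisher_z_difference(0.2, 0.7, 40, 30)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_difference(0.5, 0.1, 3, 50)


class TestDysregulationSummary:
    @pytest.mark.parametrize(
        "n,expected",
        [(276, 14), (17727, 886), (57970, 2899), (1326, 66), (145, 7)],
    )
    def test_expected_counts_round_half_up(self, n, expected):
        assert round_half_up(n * 0.05) == expected

    @pytest.mark.parametrize(
        "observed,n,p_2sf",
        [(25, 276, 5.1e-3), (16, 276, 4.9e-1), (72, 1326, 4.5e-1),
         (1054, 17727, 1.9e-8), (3751, 57970, 1.1e-54)],
    )
    def test_binomial_excess_reference_values(self, observed, n, p_2sf):
        p_vals = np.concatenate([np.full(observed, 0.01), np.full(n - observed, 0.5)])
        res = dysregulation_summary(p_vals, alpha=0.05)
        assert res.observed == observed
        assert res.p_binom == pytest.approx(p_2sf, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dysregulation_summary([])


class TestSignTest:
    def test_six_of_six(self):
        comps = [(i + 1.0, float(i)) for i in range(6)]
        assert sign_test_superiority(comps) == pytest.approx(0.015625)

    def test_zero_of_six(self):
        comps = [(float(i), i + 1.0) for i in range(6)]
        assert sign_test_superiority(comps) == pytest.approx(1.0)

    def test_three_of_six_by_enumeration(self):
        comps = [(1.0, 0.0)] * 3 + [(0.0, 1.0)] * 3
        # P(X >= 3), X ~ Bin(6, 1/2) = (20 + 15 + 6 + 1)/64
        assert sign_test_superiority(comps) == pytest.approx(42 / 64)

    def test_ties_dropped(self):
        assert sign_test_superiority([(1.0, 1.0), (2.0, 1.0)]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            sign_test_superiority([(1.0, 1.0)])


class TestPairHelpers:
    def test_all_pairs_count(self):
        assert len(all_pairs(list("abcd"))) == 6

    def test_cross_pairs_exclude_self_and_duplicates(self):
        pairs = cross_pairs(["a", "b"], ["b", "c"])
        assert ("b", "b") not in pairs
        assert len(pairs) == len(set(pairs))
        assert set(pairs) == {("a", "b"), ("a", "c"), ("b", "c")}


def test_planted_dysregulated_pairs_detected():
    cfg = SyntheticConfig(
        n_genes=60,
        n_samples_per_arm=20,
        pathways={"a": 20},
        planted_de_pathway=None,
        coexpression_blocks=[("a", 0.3)],
        dysregulated_pairs=None,
        n_dysregulated_pairs=8,
        dysregulation_delta=-0.6,
        dysregulated_pathway="a",
        gwas=GwasConfig(planted_pathway=None),
        ppi=PpiConfig(crossing_pathways=None),
        seed=21,
    )
    study, truth = generate_expression(cfg)
    cases = study.arm_matrix("case", "allergen")
    controls = study.arm_matrix("control", "allergen")
    pairs = [(a, b) for a, b, _ in truth.dysregulated_pairs]
    table = correlation_difference_table(cases, controls, pairs)
    res = dysregulation_summary(table["p"].to_numpy(), alpha=0.05)
    assert res.observed > res.expected
    assert res.p_binom < 0.05
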