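"""Generator contracts: determinism, planted-signal fidelity, degeneracy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inparkit.io import read_edge_list, write_edge_list
from inparkit.synthdata import (
    GwasConfig,
    PpiConfig,
    SyntheticConfig,
    generate_expression,
    generate_gene_coords,
    generate_gwas,
    generate_interactions,
    nearest_psd_correlation,
    simulate,
)


def _noise_config(**kw):
    base = dict(
        n_genes=40,
        n_samples_per_arm=10,
        pathways={"a": 10, "b": 10},
        planted_de_pathway=None,
        coexpression_blocks=[],
        dysregulated_pairs=[],
        gwas=GwasConfig(n_snps=500, planted_pathway=None),
        ppi=PpiConfig(density=0.0, crossing_pathways=None),
        seed=1,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def test_same_seed_reproduces_everything_exactly():
    a = simulate(SyntheticConfig(seed=42))
    b = simulate(SyntheticConfig(seed=42))
    pd.testing.assert_frame_equal(a.study.matrix, b.study.matrix)
    pd.testing.assert_frame_equal(a.gwas, b.gwas)
    assert sorted(a.interactions.edges) == sorted(b.interactions.edges)
    assert a.truth.de_effects == b.truth.de_effects
    assert a.truth.response_coefficients == b.truth.response_coefficients


def test_pure_noise_has_null_correlation_magnitude():
    # with nothing planted, mean |rho| across pairs matches the null
    # expectation sqrt(2/(pi*n)) of a sample correlation at n samples
    # (|rho| is approximately half-normal with variance 1/n)
    cfg = _noise_config(n_genes=60, n_samples_per_arm=25)
    study, _ = generate_expression(cfg)
    x = study.matrix.to_numpy()
    n = x.shape[1]
    corr = np.corrcoef(x)
    iu = np.triu_indices_from(corr, k=1)
    expected = np.sqrt(2 / (np.pi * n))
    assert abs(np.abs(corr[iu]).mean() - expected) < 0.1 * expected


def test_planted_effect_recovered_within_three_se():
    effects = [-2.0] * 10
    cfg = _noise_config(
        n_samples_per_arm=20,
        planted_de_pathway="a",
        de_effects=effects,
        noise_sd=0.5,
    )
    study, truth = generate_expression(cfg)
    gene = next(iter(truth.de_effects))
    case = study.arm_matrix("case", "allergen").loc[gene]
    ref = study.arm_matrix("case", "diluent").loc[gene]
    est = case.mean() - ref.mean()
    se = np.sqrt(case.var(ddof=1) / len(case) + ref.var(ddof=1) / len(ref))
    assert abs(est - (-2.0)) < 3 * se


def test_dysregulated_pair_correlation_shifts_in_case_allergen_arm():
    cfg = _noise_config(
        n_genes=30,
        n_samples_per_arm=200,  # large arms so sample rho is tight
        pathways={"a": 10},
        coexpression_blocks=[("a", 0.6)],
        dysregulated_pairs=None,
        n_dysregulated_pairs=5,
        dysregulation_delta=-0.6,
        dysregulated_pathway="a",
    )
    study, truth = generate_expression(cfg)
    a, b, delta = truth.dysregulated_pairs[0]
    case = study.arm_matrix("case", "allergen")
    ctrl = study.arm_matrix("control", "allergen")
    r_case = np.corrcoef(case.loc[a], case.loc[b])[0, 1]
    r_ctrl = np.corrcoef(ctrl.loc[a], ctrl.loc[b])[0, 1]
    assert r_ctrl == pytest.approx(0.6, abs=0.12)
    assert r_case - r_ctrl == pytest.approx(delta, abs=0.17)


def test_psd_repair_failure_names_offending_pairs():
    # three mutually inconsistent extreme correlations cannot survive projection
    cfg = _noise_config(
        n_genes=10,
        pathways={"a": 3},
        coexpression_blocks=[("a", 0.9)],
        dysregulated_pairs=[
            ("G01", "G02", -1.8), ("G01", "G03", -1.8), ("G02", "G03", -1.8),
        ],
    )
    with pytest.raises(ValueError, match="PSD repair"):
        generate_expression(cfg)


def test_truth_names_only_measured_genes(default_bundle):
    genes = set(default_bundle.study.matrix.index)
    t = default_bundle.truth
    assert set(t.de_effects) <= genes
    assert {g for pair in t.dysregulated_pairs for g in pair[:2]} <= genes
    assert set(t.gwas_genes) <= genes
    assert {g for e in t.crossing_edges for g in e} <= genes
    assert set(t.response_coefficients) <= genes


class TestGwasGenerator:
    def test_null_pvalues_uniform_over_seeds(self):
        # calibration: KS uniformity of the pooled null p-values, 20 seeds
        ks_ps = []
        for seed in range(20):
            cfg = _noise_config(seed=seed, gwas=GwasConfig(n_snps=300, planted_pathway=None))
            coords = generate_gene_coords(cfg)
            gwas = generate_gwas(cfg, coords)
            ks_ps.append(stats.kstest(gwas["p"], "uniform").pvalue)
        assert stats.kstest(ks_ps, "uniform").pvalue > 0.01

    def test_planted_genes_receive_low_p_window_snp(self):
        cfg = _noise_config(gwas=GwasConfig(n_snps=200, planted_pathway="a", planted_fraction=1.0, beta_a=0.1))
        coords = generate_gene_coords(cfg)
        from inparkit.synthdata import SyntheticTruth

        truth = SyntheticTruth(seed=cfg.seed)
        gwas = generate_gwas(cfg, coords, truth)
        lookup = coords.set_index("gene")
        for gene in truth.gwas_genes:
            start, end = lookup.loc[gene, ["start", "end"]]
            in_window = gwas[
                (gwas["chrom"] == lookup.loc[gene, "chrom"])
                & (gwas["pos"] >= start + 1 - 50_000)
                & (gwas["pos"] <= end + 50_000)
            ]
            assert len(in_window) >= 1

    def test_zero_snps_and_no_planting_gives_empty_table(self):
        cfg = _noise_config(gwas=GwasConfig(n_snps=0, planted_pathway=None))
        gwas = generate_gwas(cfg, generate_gene_coords(cfg))
        assert gwas.empty


class TestInteractionGenerator:
    def test_density_zero_keeps_only_planted_edges(self):
        cfg = _noise_config(
            ppi=PpiConfig(density=0.0, crossing_pathways=("a", "b"), n_crossing_edges=3)
        )
        g = generate_interactions(cfg)
        assert g.number_of_edges() == 3

    def test_edge_count_matches_binomial_expectation(self):
        cfg = _noise_config(
            n_genes=500,
            pathways={},
            ppi=PpiConfig(density=0.01, crossing_pathways=None),
        )
        g = generate_interactions(cfg)
        n_pairs = 500 * 499 // 2
        mean = 0.01 * n_pairs
        sd = np.sqrt(n_pairs * 0.01 * 0.99)
        assert abs(g.number_of_edges() - mean) < 4 * sd

    def test_planted_edges_survive_edge_list_round_trip(self, tmp_path):
        cfg = _noise_config(
            ppi=PpiConfig(density=0.02, crossing_pathways=("a", "b"), n_crossing_edges=4)
        )
        from inparkit.synthdata import SyntheticTruth

        truth = SyntheticTruth(seed=cfg.seed)
        g = generate_interactions(cfg, truth)
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        g2 = read_edge_list(path)
        for a, b in truth.crossing_edges:
            assert g2.has_edge(a, b)
            assert g2[a][b]["type"] == "direct"

    def test_planted_edge_between_absent_pathway_raises(self):
        cfg = _noise_config(ppi=PpiConfig(density=0.0, crossing_pathways=("a", "zz"), n_crossing_edges=1))
        with pytest.raises(KeyError):
            generate_interactions(cfg)


def test_nearest_psd_projection_fixes_indefinite_matrix():
    c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_psd_correlation(c)
    vals = np.linalg.eigvalsh(fixed)
    assert vals.min() >= 0
    assert np.allclose(np.diag(fixed), 1.0)
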