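"""End-to-end analysis chain on one synthetic (or user-supplied) study.

The chain mirrors the analysis strategy the package implements:
differential expression of the allergen response, expression-side
gene-set enrichment, GWAS-side enrichment via best-SNP gene scores,
Pareto co-enrichment prioritisation, inter-pathway network extraction
and connectivity testing, coordination-dysregulation statistics, and
predictive regression of the protein response on the network genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coenrich, coordination, diffexpr, genesets, gwasmap, inparnet, th2pred
from .genesets import GeneSetCollection
from .synthdata import SyntheticConfig, SyntheticStudy, simulate


@dataclass
class PipelineResult:
    de: pd.DataFrame
    expr_enrichment: list[genesets.EnrichmentRecord]
    gwas_scores: pd.DataFrame
    gwas_enrichment: pd.DataFrame
    coenrichment: pd.DataFrame
    selected_pathway: str | None
    inpar: inparnet.InparNetwork
    connectivity: inparnet.InparNetwork | None
    correlation_enrichment: coordination.CorrelationEnrichment | None
    dysregulation: dict[str, coordination.CoordinationResult]
    regression: th2pred.RegressionReport | None


def run_pipeline(
    config: SyntheticConfig,
    data: SyntheticStudy | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    sig_q: float = 0.05,
    sig_log2: float = 1.0,
    connectivity_perm: int = 0,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full chain; ``data`` defaults to ``simulate(config)``.

    ``connectivity_perm=0`` skips the (comparatively slow) network
    connectivity permutation test.
    """
    if data is None:
        data = simulate(config)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 97])
    collection = GeneSetCollection({k: set(v) for k, v in data.gene_sets.items()})

    # 1. differential expression of the allergen response in cases
    de = diffexpr.differential_expression(data.study, "case_allergen-vs-case_diluent")

    # 2. expression-side enrichment
    records = genesets.enrich_gene_sets(
        de, collection, sig_q=sig_q, sig_log2=sig_log2, n_perm=n_perm,
        seed=int(rng.integers(2**31)),
    )
    expr_table = pd.DataFrame(
        {
            "p_hyper": [r.p_hyper for r in records],
            "p_gsea": [r.p_gsea for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
        },
        index=pd.Index([r.name for r in records], name="set"),
    )

    # 3. GWAS-side enrichment
    scores = gwasmap.map_genes_to_best_snp(data.gwas, data.gene_coords, window=config.gwas.window)
    gwas_enr = gwasmap.magenta_enrichment(
        scores, collection, n_perm=n_perm, seed=int(rng.integers(2**31))
    )

    # 4. co-enrichment and Pareto prioritisation
    co_records = coenrich.make_records(expr_table, gwas_enr)
    ranked = coenrich.prioritize_pathways(co_records, bound=alpha)
    co_table = coenrich.records_to_frame(co_records)
    selected = ranked[0].name if ranked else None

    # 5. inter-pathway network between the two designated pathways
    if config.ppi.crossing_pathways is not None:
        a_name, b_name = config.ppi.crossing_pathways
    else:
        names = list(collection)
        a_name, b_name = names[0], names[1]
    net = inparnet.extract_inpar_network(
        data.interactions, set(collection[a_name]), set(collection[b_name])
    )
    conn = None
    if connectivity_perm and net.members:
        conn = inparnet.connectivity_enrichment(
            net.members, data.interactions, n_perm=connectivity_perm,
            seed=int(rng.integers(2**31)),
        )

    # 6. coordination: network co-expression and case/control dysregulation
    corr_enr = None
    if len(net.members & set(data.study.matrix.index)) >= 2:
        corr_enr = coordination.correlation_enrichment(
            data.study.matrix, net.members, n_perm=n_perm,
            seed=int(rng.integers(2**31)), name="INPAR-N",
        )
    dys: dict[str, coordination.CoordinationResult] = {}
    for condition in ("allergen", "diluent"):
        cases = data.study.arm_matrix("case", condition)
        controls = data.study.arm_matrix("control", condition)
        pairs = coordination.all_pairs(sorted(collection[config.dysregulated_pathway]))
        table = coordination.correlation_difference_table(cases, controls, pairs)
        dys[condition] = coordination.dysregulation_summary(
            table["p"].to_numpy(), alpha=alpha,
            name=config.dysregulated_pathway, condition=condition,
        )

    # 7. predictive regression of the protein response on network genes
    regression = None
    predictors = sorted(net.members & set(data.study.matrix.index))
    if len(predictors) >= 2:
        X = data.study.matrix.loc[predictors].T
        regression = th2pred.crossval_q2_regression(
            X, data.protein, k_folds=7, n_perm=n_perm, seed=int(rng.integers(2**31))
        )

    return PipelineResult(
        de=de,
        expr_enrichment=records,
        gwas_scores=scores,
        gwas_enrichment=gwas_enr,
        coenrichment=co_table,
        selected_pathway=selected,
        inpar=net,
        connectivity=conn,
        correlation_enrichment=corr_enr,
        dysregulation=dys,
        regression=regression,
    )
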