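"""Gene-set enrichment of differential-expression results.

Two complementary tests are provided: the hypergeometric
over-representation test on a hard significant/not-significant gene
split, and a running-sum GSEA on the full ranking. Their conjunction
after Benjamini-Hochberg correction gives the consensus list used for
downstream co-enrichment. Enrichment odds ratios from several studies
are pooled with a Mantel-Haenszel meta-analysis, and Jaccard overlap
maps summarise redundancy between the sets themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag (KEGG / GO / custom)."""

    sets: dict[str, set[str]]
    source: str = "custom"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restrict(self, universe: set[str] | list[str]) -> "GeneSetCollection":
        """Intersect every set with the measured-gene universe, dropping
        sets that become empty."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & uni
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r has no overlap with universe; dropped", name)
        return GeneSetCollection(kept, source=self.source)


@dataclass
class EnrichmentRecord:
    """Enrichment summary of one gene set against one DE result."""

    name: str
    k: int  # significant genes in set
    K: int  # set size within universe
    n: int  # significant genes
    N: int  # universe size
    odds_ratio: float
    p_hyper: float
    es: float = np.nan
    p_gsea: float = np.nan
    q_hyper: float = np.nan
    q_gsea: float = np.nan
    consensus: bool = False


def hypergeometric_enrichment(
    significant: set[str] | list[str],
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
) -> EnrichmentRecord:
    """One-sided upper-tail hypergeometric enrichment of a gene set.

    The 2x2 table counts the overlap k of the significant list (size n)
    with the set (size K) inside the universe (size N). The odds ratio
    is k(N-n-K+k) / ((K-k)(n-k)); when any cell is zero every cell gets
    the Haldane-Anscombe 0.5 correction before the ratio is formed.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = set(significant) & uni
    members = set(gene_set) & uni
    N, K, n = len(uni), len(members), len(sig)
    k = len(sig & members)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    return EnrichmentRecord(
        name="", k=k, K=K, n=n, N=N, odds_ratio=float(odds_ratio), p_hyper=min(p, 1.0)
    )


def gsea_running_sum(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed maximum deviation of the GSEA running sum.

    Genes in the set advance the sum by |score|^weight_exponent
    normalised over in-set scores; genes outside retreat by 1/(N-K).
    """
    hits = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    K = int(hits.sum())
    N = len(ranked_genes)
    if K == 0 or K == N:
        raise ValueError("gene set must overlap the ranking partially")
    w = np.abs(np.asarray(scores, float)) ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores zero: fall back to unweighted steps
        hit_w = hits / K
    else:
        hit_w = hit_w / total
    steps = hit_w - (~hits) / (N - K)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_enrichment(
    ranked: pd.Series | tuple[list[str], np.ndarray],
    gene_set: set[str],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
) -> tuple[float, float]:
    """GSEA enrichment score and gene-label permutation p-value.

    ``ranked`` is a Series of scores indexed by gene, sorted descending
    (or an explicit (genes, scores) pair). The null redraws K gene
    labels uniformly ``n_perm`` times; the p-value is one-sided in the
    direction of the observed score and, to stay calibrated despite the
    signed-maximum selection, is computed against the same-signed part
    of the null distribution only, with add-one correction.
    """
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index)
        scores = ranked.to_numpy(float)
    else:
        genes, scores = list(ranked[0]), np.asarray(ranked[1], float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    es = gsea_running_sum(genes, scores, members, weight_exponent)
    K = len(members)
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes, dtype=object)
    same_sign = 0
    exceed = 0
    for _ in range(n_perm):
        null_set = set(rng.choice(gene_arr, size=K, replace=False))
        es_null = gsea_running_sum(genes, scores, null_set, weight_exponent)
        if es >= 0 and es_null >= 0:
            same_sign += 1
            exceed += es_null >= es
        elif es < 0 and es_null < 0:
            same_sign += 1
            exceed += es_null <= es
    p = (exceed + 1) / (same_sign + 1)
    return es, float(p)


def bh_qvalues(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_sets(
    de: pd.DataFrame,
    collection: GeneSetCollection,
    sig_q: float = 0.05,
    sig_log2: float = 1.0,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric + GSEA enrichment of every set against a DE table.

    ``de`` is the output of :func:`inparkit.diffexpr.differential_expression`.
    Significant genes for the hypergeometric split are those with
    ``q < sig_q`` and ``|log2_ratio| > sig_log2``; the GSEA ranking is by
    the signed t statistic. BH q-values are computed across sets for each
    test and the consensus flag marks sets significant under both at the
    ``sig_q`` level.
    """
    universe = set(de.index)
    restricted = collection.restrict(universe)
    significant = set(de.index[(de["q"] < sig_q) & (de["log2_ratio"].abs() > sig_log2)])
    ranked = de["stat"].sort_values(ascending=False)
    records: list[EnrichmentRecord] = []
    rng = np.random.default_rng(seed)
    for name, members in restricted.items():
        rec = hypergeometric_enrichment(significant, members, universe)
        rec.name = name
        try:
            rec.es, rec.p_gsea = gsea_enrichment(
                ranked, members, n_perm=n_perm, weight_exponent=weight_exponent,
                seed=int(rng.integers(2**31)),
            )
        except ValueError:
            logger.warning("set %r skipped for GSEA (no usable overlap)", name)
        records.append(rec)
    if records:
        qh = bh_qvalues([r.p_hyper for r in records])
        pg = np.array([r.p_gsea for r in records])
        qg = np.full(len(records), np.nan)
        ok = ~np.isnan(pg)
        if ok.any():
            qg[ok] = bh_qvalues(pg[ok])
        for rec, a, b in zip(records, qh, qg):
            rec.q_hyper, rec.q_gsea = float(a), float(b)
    return records


def consensus_enriched(records: list[EnrichmentRecord], fdr: float = 0.05) -> list[EnrichmentRecord]:
    """Sets significant under both tests after BH correction (inclusive)."""
    out = []
    for rec in records:
        rec.consensus = bool(
            not np.isnan(rec.q_hyper) and not np.isnan(rec.q_gsea)
            and rec.q_hyper <= fdr and rec.q_gsea <= fdr
        )
        if rec.consensus:
            out.append(rec)
    return out


def jaccard_overlap_map(collection: GeneSetCollection, min_jaccard: float = 0.1) -> nx.Graph:
    """Weighted overlap graph between gene sets (edges where J >= threshold, J > 0)."""
    g = nx.Graph()
    names = list(collection)
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = collection[a], collection[b]
            j = len(sa & sb) / len(sa | sb)
            if j > 0 and j >= min_jaccard:
                g.add_edge(a, b, weight=j)
    return g


def mh_meta_or(tables: list[np.ndarray]) -> dict[str, float]:
    """Mantel-Haenszel meta-analysis of 2x2 enrichment tables.

    Returns the pooled odds ratio, its two-sided p-value, the Woolf
    heterogeneity test p-value, and a ``heterogeneous`` flag raised when
    the heterogeneity p is <= 0.2.
    """
    if len(tables) < 2:
        raise ValueError("Mantel-Haenszel meta-analysis requires >=2 tables")
    clean = []
    for t in tables:
        t = np.asarray(t, float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("tables must be non-negative 2x2")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            logger.warning("table with an all-zero margin excluded from meta-analysis")
            continue
        clean.append(t)
    if len(clean) < 2:
        raise ValueError("fewer than 2 usable tables after margin filtering")
    strat = StratifiedTable(np.stack(clean, axis=-1))
    pooled_or = float(strat.oddsratio_pooled)
    p = float(strat.test_null_odds(correction=False).pvalue)
    # Woolf heterogeneity: chi-square of Haldane-corrected log ORs about
    # their inverse-variance weighted mean
    log_or, var = [], []
    for t in clean:
        a, b, c, d = (t + 0.5).ravel()
        log_or.append(np.log(a * d / (b * c)))
        var.append(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.array(log_or)
    w = 1.0 / np.array(var)
    mean_lor = (w * log_or).sum() / w.sum()
    x2 = float((w * (log_or - mean_lor) ** 2).sum())
    p_het = float(stats.chi2.sf(x2, len(clean) - 1))
    return {
        "or_pooled": pooled_or,
        "p": p,
        "p_heterogeneity": p_het,
        "heterogeneous": p_het <= 0.2,
    }
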