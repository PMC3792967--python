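"""Pathway enrichment of GWAS summary statistics.

Follows the MAGENTA idea at its core: each gene is scored by the most
significant SNP within a fixed window around its span (50 kb by
default), and a gene set is called enriched when it holds more
high-scoring genes than random same-size draws from the scored genome.
The gene-score confounder regression of full MAGENTA (gene size, SNP
density, LD) is intentionally not applied; scores are raw best-SNP
p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, bh_qvalues

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ("snp", "chrom", "pos", "p")


def map_genes_to_best_snp(
    gwas: pd.DataFrame,
    coords: pd.DataFrame,
    window: int = 50_000,
) -> pd.DataFrame:
    """Score every gene by its best SNP p-value within +-``window`` bp.

    ``gwas`` needs columns ``snp, chrom, pos, p`` (1-based positions);
    ``coords`` needs ``gene, chrom, start, end`` with BED-style 0-based
    half-open spans. A SNP is eligible for a gene spanning 1-based
    [start+1, end] when ``start+1-window <= pos <= end+window``
    (inclusive on both sides). Genes without any eligible SNP are left
    out of the result and counted in the log.

    Returns a DataFrame indexed by gene with columns
    ``best_snp, best_p, n_snps``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    bad = coords[coords["end"] <= coords["start"]]
    if len(bad):
        raise ValueError(f"malformed coordinates (end <= start) for genes {list(bad['gene'])[:5]}")
    rows = []
    n_empty = 0
    for chrom, genes_c in coords.groupby("chrom"):
        snps_c = gwas[gwas["chrom"] == chrom]
        if snps_c.empty:
            n_empty += len(genes_c)
            continue
        pos = snps_c["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        pvals = snps_c["p"].to_numpy(float)[order]
        snp_ids = snps_c["snp"].to_numpy(object)[order]
        for gene, start, end in genes_c[["gene", "start", "end"]].itertuples(index=False):
            lo = start + 1 - window  # 1-based inclusive bounds
            hi = end + window
            i = np.searchsorted(pos, lo, side="left")
            j = np.searchsorted(pos, hi, side="right")
            if i == j:
                n_empty += 1
                continue
            best = i + int(np.argmin(pvals[i:j]))
            rows.append((gene, snp_ids[best], float(pvals[best]), int(j - i)))
    if n_empty:
        logger.info("%d genes had no SNP within the window and were dropped", n_empty)
    out = pd.DataFrame(rows, columns=["gene", "best_snp", "best_p", "n_snps"])
    return out.set_index("gene")


def magenta_enrichment(
    scores: pd.DataFrame,
    collection: GeneSetCollection,
    cutoff_quantile: float = 0.95,
    n_perm: int = 10_000,
    seed: int | None = None,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Permutation enrichment of gene sets for high GWAS gene scores.

    The threshold is the ``cutoff_quantile`` of -log10(best p) over all
    scored genes. For each set, the observed statistic is the number of
    member genes above the threshold; the null draws equally sized gene
    sets uniformly from the scored genes, and
    p = (draws with observed-or-more + 1)/(n_perm + 1). BH FDR is
    computed across sets; ``enriched`` flags sets at p <= 0.05 and
    FDR <= 0.25.
    """
    if scores.empty:
        raise ValueError("empty gene-score table")
    neglog = -np.log10(scores["best_p"].to_numpy(float))
    genes = scores.index.to_numpy(object)
    threshold = float(np.quantile(neglog, cutoff_quantile))
    above = neglog >= threshold
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.restrict(set(genes)).items():
        idx = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
        K = int(idx.sum())
        if K < min_set_size:
            logger.warning("set %r has %d scored genes (<%d); skipped", name, K, min_set_size)
            continue
        observed = int((idx & above).sum())
        null_counts = np.empty(n_perm, dtype=np.int64)
        for b in range(n_perm):
            draw = rng.choice(len(genes), size=K, replace=False)
            null_counts[b] = above[draw].sum()
        p = (int((null_counts >= observed).sum()) + 1) / (n_perm + 1)
        rows.append((name, K, observed, float(np.mean(null_counts)), p))
    out = pd.DataFrame(
        rows, columns=["set", "n_scored", "observed_above", "expected_above", "p"]
    ).set_index("set")
    if len(out):
        out["fdr"] = bh_qvalues(out["p"].to_numpy())
        out["enriched"] = (out["p"] <= 0.05) & (out["fdr"] <= 0.25)
    return out
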