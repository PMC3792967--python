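"""Synthetic study generator.

Emulates the statistical design the pipeline expects — a 2-group
(case/control) x 2-challenge (allergen/diluent) expression study with
paired cultures, GWAS summary statistics, pathway annotations, a
protein-interaction graph and a protein-level response — with planted,
recorded signals so every downstream stage can be tested for
calibration and recovery without any external download.

Planted structure:

* pathway-level differential expression in the case-allergen arm (log2
  shifts on the genes of one pathway),
* block co-expression within designated pathways (equicorrelated
  multivariate-normal blocks),
* case-specific correlation disruption of designated gene pairs under
  allergen challenge,
* GWAS p-value enrichment near the genes of one pathway (Beta(a, 1)
  alternative SNPs inside the gene windows),
* direct protein interactions crossing two pathways (the background
  Erdos-Renyi graph deliberately avoids that crossing stratum so the
  planted edges are exactly the inter-pathway signal),
* a protein response that is a noisy linear function of designated
  genes.

Everything planted is recorded in :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionStudy

ARMS = [("case", "allergen"), ("case", "diluent"), ("control", "allergen"), ("control", "diluent")]
PSD_EIG_FLOOR = 1e-8
PSD_REPAIR_TOL = 0.1


@dataclass
class GwasConfig:
    n_snps: int = 5000
    chrom_lengths: dict[str, int] | None = None  # default derived from gene coords
    planted_pathway: str | None = "Complement_system"
    planted_fraction: float = 0.5
    beta_a: float = 0.1  # alternative p ~ Beta(a, 1), a < 1
    window: int = 50_000


@dataclass
class PpiConfig:
    density: float = 0.01
    crossing_pathways: tuple[str, str] | None = ("T_cell_activation", "Complement_system")
    n_crossing_edges: int = 10


@dataclass
class ResponseConfig:
    target_genes: list[str] | None = None  # default: first 5 planted crossing-edge genes
    coefficients: list[float] | None = None  # default: |U(0.5, 1.5)| with random sign
    noise_fraction: float = 0.5  # noise sd as a fraction of the signal sd


@dataclass
class SyntheticConfig:
    """Full parameterisation of one synthetic study.

    Defaults emulate a small allergen-challenge microarray study: 300
    measured genes of which six pathways cover 160, twenty samples per
    arm of the 2x2 design, Gaussian log2-scale noise with sd 0.5,
    planted log2 effects with magnitudes in [0.3, 2.7] on one pathway,
    modest within-pathway co-expression (rho = 0.3), and fifteen gene
    pairs whose case-arm correlation under allergen is shifted by -0.6.
    """

    n_genes: int = 300
    n_samples_per_arm: int = 20
    noise_sd: float = 0.5
    baseline: float = 8.0
    pathways: dict[str, int] = field(
        default_factory=lambda: {
            "T_cell_activation": 40,
            "Complement_system": 30,
            "decoy_1": 25,
            "decoy_2": 25,
            "decoy_3": 20,
            "decoy_4": 20,
        }
    )
    planted_de_pathway: str | None = "Complement_system"
    de_effects: list[float] | None = None  # default: magnitudes U(0.3, 2.7), random sign
    de_effect_range: tuple[float, float] = (0.3, 2.7)
    coexpression_blocks: list[tuple[str, float]] = field(
        default_factory=lambda: [("T_cell_activation", 0.3), ("Complement_system", 0.3)]
    )
    dysregulated_pairs: list[tuple[str, str, float]] | None = None  # default: 15 pairs, delta -0.6
    n_dysregulated_pairs: int = 15
    dysregulation_delta: float = -0.6
    dysregulated_pathway: str = "T_cell_activation"
    gwas: GwasConfig = field(default_factory=GwasConfig)
    ppi: PpiConfig = field(default_factory=PpiConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_arm <= 0:
            raise ValueError("sizes must be positive")
        if sum(self.pathways.values()) > self.n_genes:
            raise ValueError("pathway sizes exceed the number of genes")
        for _, rho in self.coexpression_blocks:
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"within-block correlation {rho} outside [0, 1)")

    # -- deterministic derived structure ------------------------------------
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def pathway_members(self) -> dict[str, list[str]]:
        """Assign consecutive disjoint gene blocks to the named pathways."""
        genes = self.gene_names()
        out = {}
        start = 0
        for name, size in self.pathways.items():
            out[name] = genes[start:start + size]
            start += size
        return out

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticTruth:
    """Record of every planted signal, serialisable to JSON."""

    seed: int
    de_pathway: str | None = None
    de_effects: dict[str, float] = field(default_factory=dict)
    dysregulated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    gwas_pathway: str | None = None
    gwas_genes: list[str] = field(default_factory=list)
    crossing_edges: list[tuple[str, str]] = field(default_factory=list)
    response_coefficients: dict[str, float] = field(default_factory=dict)
    pathway_members: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["dysregulated_pairs"] = [tuple(x) for x in d["dysregulated_pairs"]]
        d["crossing_edges"] = [tuple(x) for x in d["crossing_edges"]]
        return cls(**d)


def nearest_psd_correlation(c: np.ndarray, eig_floor: float = PSD_EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix by
    eigenvalue clipping followed by unit-diagonal rescaling."""
    c = (c + c.T) / 2
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= eig_floor:
        return c
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _resolve_dysregulated_pairs(config: SyntheticConfig) -> list[tuple[str, str, float]]:
    """Draw disjoint gene pairs (each gene used at most once) so the
    perturbed correlation matrix stays positive semi-definite: with an
    equicorrelated block at rho and disjoint deltas, the smallest
    eigenvalue is bounded below by (1 - rho) - |delta|."""
    if config.dysregulated_pairs is not None:
        return list(config.dysregulated_pairs)
    members = config.pathway_members().get(config.dysregulated_pathway, [])
    if len(members) < 2:
        return []
    n_pairs = min(config.n_dysregulated_pairs, len(members) // 2)
    rng = config._rng(11)
    order = rng.permutation(len(members))
    return [
        (members[order[2 * k]], members[order[2 * k + 1]], config.dysregulation_delta)
        for k in range(n_pairs)
    ]


def _base_correlation(config: SyntheticConfig, gene_idx: dict[str, int]) -> np.ndarray:
    c = np.eye(config.n_genes)
    members = config.pathway_members()
    for name, rho in config.coexpression_blocks:
        idx = [gene_idx[g] for g in (members[name] if name in members else [name])]
        for i in idx:
            for j in idx:
                if i != j:
                    c[i, j] = rho
    return c


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Generate the 2x2 expression study and its ground-truth record.

    The case-allergen arm carries the planted log2 shifts of the DE
    pathway; the designated gene pairs have their correlation shifted by
    the stated delta in the case-allergen arm only, so the allergen
    condition compares dysregulated cases to intact controls while the
    diluent condition is null. Non-PSD target matrices are repaired by
    eigenvalue clipping; if the repair moves a planted pair correlation
    by more than 0.1 the offending pairs are reported in the error.
    """
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    members = config.pathway_members()
    truth = SyntheticTruth(seed=config.seed, pathway_members=members)

    # planted differential expression (case-allergen arm)
    effects = np.zeros(config.n_genes)
    if config.planted_de_pathway is not None:
        de_genes = members[config.planted_de_pathway]
        if config.de_effects is not None:
            if len(config.de_effects) != len(de_genes):
                raise ValueError("de_effects length must equal the planted pathway size")
            vals = np.asarray(config.de_effects, float)
        else:
            # magnitudes span the observed fold-change range; signs are
            # predominantly negative, mirroring the coherent down-regulation
            # a challenged pathway shows (GSEA needs directional coherence)
            rng_e = config._rng(7)
            lo, hi = config.de_effect_range
            signs = np.where(rng_e.random(len(de_genes)) < 0.8, -1.0, 1.0)
            vals = rng_e.uniform(lo, hi, size=len(de_genes)) * signs
        for g, v in zip(de_genes, vals):
            effects[gene_idx[g]] = v
        truth.de_pathway = config.planted_de_pathway
        truth.de_effects = {g: float(v) for g, v in zip(de_genes, vals)}

    pairs = _resolve_dysregulated_pairs(config)
    for a, b, _ in pairs:
        if a not in gene_idx or b not in gene_idx:
            raise ValueError(f"dysregulated pair ({a}, {b}) names an absent gene")
    truth.dysregulated_pairs = pairs

    base = _base_correlation(config, gene_idx)
    disrupted = base.copy()
    for a, b, delta in pairs:
        i, j = gene_idx[a], gene_idx[b]
        target = float(np.clip(disrupted[i, j] + delta, -0.99, 0.99))
        disrupted[i, j] = disrupted[j, i] = target
    base_psd = nearest_psd_correlation(base)
    disrupted_psd = nearest_psd_correlation(disrupted)
    offending = [
        (a, b)
        for a, b, _ in pairs
        if abs(disrupted_psd[gene_idx[a], gene_idx[b]] - disrupted[gene_idx[a], gene_idx[b]])
        > PSD_REPAIR_TOL
    ]
    if offending:
        raise ValueError(
            "PSD repair moved the planted correlation of pairs "
            f"{offending[:10]} by more than {PSD_REPAIR_TOL}"
        )

    chol_base = np.linalg.cholesky(base_psd + PSD_EIG_FLOOR * np.eye(config.n_genes))
    chol_disrupted = np.linalg.cholesky(disrupted_psd + PSD_EIG_FLOOR * np.eye(config.n_genes))

    rng = config._rng(1)
    columns, data, annot = [], [], []
    n = config.n_samples_per_arm
    for group, challenge in ARMS:
        chol = chol_disrupted if (group, challenge) == ("case", "allergen") else chol_base
        z = rng.standard_normal((config.n_genes, n))
        x = config.baseline + config.noise_sd * (chol @ z)
        if (group, challenge) == ("case", "allergen"):
            x = x + effects[:, None]
        for k in range(n):
            sid = f"{group}_{challenge}_{k + 1:02d}"
            columns.append(sid)
            annot.append((sid, group, challenge, f"{group}_{k + 1:02d}"))
        data.append(x)
    matrix = pd.DataFrame(np.concatenate(data, axis=1), index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(annot, columns=["sample", "group", "challenge", "pairing"]).set_index("sample")
    return ExpressionStudy(matrix=matrix, samples=samples, log2_scale=True), truth


def generate_gene_coords(config: SyntheticConfig, gene_length: int = 5_000, spacing: int = 150_000) -> pd.DataFrame:
    """BED-style (0-based half-open) coordinates: genes tiled along one
    chromosome, spaced widely enough that 50 kb windows never overlap."""
    rows = []
    for i, gene in enumerate(config.gene_names()):
        start = 100_000 + i * spacing
        rows.append((gene, "1", start, start + gene_length))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def generate_gwas(
    config: SyntheticConfig,
    gene_coords: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """GWAS summary statistics with a planted near-gene signal.

    Null SNPs have i.i.d. Uniform(0,1) p-values at uniform positions.
    For a random ``planted_fraction`` of the planted pathway's genes,
    one extra SNP is placed at the gene midpoint with
    p ~ Beta(a, 1), a < 1, so the smallest p in that gene's window is
    stochastically small. Positions are 1-based.
    """
    g = config.gwas
    coords = gene_coords.set_index("gene")
    if g.chrom_lengths:
        chroms = list(g.chrom_lengths)
        lengths = np.array([g.chrom_lengths[c] for c in chroms], dtype=np.int64)
    else:
        chroms = list(coords["chrom"].unique())
        lengths = np.array(
            [int(coords.loc[coords["chrom"] == c, "end"].max()) + 200_000 for c in chroms],
            dtype=np.int64,
        )
    rng = config._rng(2)
    rows = []
    if g.n_snps > 0:
        probs = lengths / lengths.sum()
        chrom_pick = rng.choice(len(chroms), size=g.n_snps, p=probs)
        for i in range(g.n_snps):
            c = chrom_pick[i]
            pos = int(rng.integers(1, lengths[c] + 1))
            rows.append((f"snp{i + 1:06d}", chroms[c], pos, float(rng.uniform())))
    planted_genes: list[str] = []
    if g.planted_pathway is not None and g.planted_fraction > 0:
        members = config.pathway_members()[g.planted_pathway]
        n_pick = int(np.ceil(g.planted_fraction * len(members)))
        picked = list(rng.choice(np.array(members, dtype=object), size=n_pick, replace=False))
        for j, gene in enumerate(picked):
            if gene not in coords.index:
                raise ValueError(f"planted gene {gene!r} missing from the coordinate table")
            start, end = int(coords.loc[gene, "start"]), int(coords.loc[gene, "end"])
            pos = (start + 1 + end) // 2
            p = float(rng.beta(g.beta_a, 1.0))
            rows.append((f"snp_causal{j + 1:03d}", str(coords.loc[gene, "chrom"]), pos, p))
        planted_genes = [str(x) for x in picked]
    if truth is not None:
        truth.gwas_pathway = g.planted_pathway if planted_genes else None
        truth.gwas_genes = planted_genes
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])


def generate_interactions(
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
) -> nx.Graph:
    """Protein-interaction graph: Erdos-Renyi background plus planted
    direct edges crossing two pathways.

    Background edges are drawn at the configured density over all gene
    pairs *except* the crossing stratum between the two designated
    pathways, so the planted edges are exactly the direct inter-pathway
    signal. All edges are flagged direct with a synthetic evidence tag.
    """
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    members = config.pathway_members()
    ppi = config.ppi
    cross_pairs: set[tuple[int, int]] = set()
    planted: list[tuple[str, str]] = []
    if ppi.crossing_pathways is not None:
        a_name, b_name = ppi.crossing_pathways
        a_set, b_set = members[a_name], members[b_name]
        for a in a_set:
            for b in b_set:
                if a == b:
                    continue
                i, j = gene_idx[a], gene_idx[b]
                cross_pairs.add((min(i, j), max(i, j)))
        rng = config._rng(3)
        candidates = sorted(cross_pairs)
        if ppi.n_crossing_edges > len(candidates):
            raise ValueError("more crossing edges requested than available pathway pairs")
        pick = rng.choice(len(candidates), size=ppi.n_crossing_edges, replace=False)
        planted = [(genes[candidates[k][0]], genes[candidates[k][1]]) for k in sorted(pick)]

    g = nx.Graph()
    g.add_nodes_from(genes)
    if ppi.density > 0:
        rng_bg = config._rng(4)
        iu = np.triu_indices(config.n_genes, k=1)
        keep = rng_bg.random(len(iu[0])) < ppi.density
        for i, j in zip(iu[0][keep], iu[1][keep]):
            if (int(i), int(j)) in cross_pairs:
                continue
            g.add_edge(genes[i], genes[j], type="direct", evidence="synthetic-background")
    for a, b in planted:
        g.add_edge(a, b, type="direct", evidence="synthetic-planted")
    if truth is not None:
        truth.crossing_edges = [tuple(sorted(e)) for e in planted]
    return g


def generate_protein_response(
    config: SyntheticConfig,
    study: ExpressionStudy,
    truth: SyntheticTruth | None = None,
) -> pd.Series:
    """Protein-level response: a noisy linear function of target genes.

    Default targets are the first five genes incident to the planted
    crossing edges (falling back to the planted DE pathway); default
    coefficients have magnitude U(0.5, 1.5) with random sign. Noise sd
    is ``noise_fraction`` times the sd of the noiseless signal.
    """
    r = config.response
    targets = r.target_genes
    if targets is None:
        if truth is not None and truth.crossing_edges:
            seen: list[str] = []
            for a, b in truth.crossing_edges:
                for gname in (a, b):
                    if gname not in seen:
                        seen.append(gname)
            targets = seen[:5]
        elif config.planted_de_pathway is not None:
            targets = config.pathway_members()[config.planted_de_pathway][:5]
        else:
            targets = config.gene_names()[:5]
    missing = [t for t in targets if t not in study.matrix.index]
    if missing:
        raise ValueError(f"response target genes absent from the matrix: {missing}")
    rng = config._rng(5)
    if r.coefficients is not None:
        if len(r.coefficients) != len(targets):
            raise ValueError("coefficient vector length must match target genes")
        coefs = np.asarray(r.coefficients, float)
    else:
        coefs = rng.uniform(0.5, 1.5, size=len(targets)) * rng.choice([-1.0, 1.0], size=len(targets))
    signal = coefs @ study.matrix.loc[targets].to_numpy(float)
    sd_signal = float(np.std(signal, ddof=1))
    noise_sd = r.noise_fraction * (sd_signal if sd_signal > 0 else 1.0)
    y = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if truth is not None:
        truth.response_coefficients = {t: float(c) for t, c in zip(targets, coefs)}
    return pd.Series(y, index=study.matrix.columns, name="protein_response")


@dataclass
class SyntheticStudy:
    """Bundle of all generated inputs for one synthetic run."""

    study: ExpressionStudy
    gene_coords: pd.DataFrame
    gwas: pd.DataFrame
    interactions: nx.Graph
    protein: pd.Series
    gene_sets: dict[str, list[str]]
    truth: SyntheticTruth


def simulate(config: SyntheticConfig) -> SyntheticStudy:
    """Generate every input of the pipeline for one seed."""
    study, truth = generate_expression(config)
    coords = generate_gene_coords(config)
    gwas = generate_gwas(config, coords, truth)
    graph = generate_interactions(config, truth)
    protein = generate_protein_response(config, study, truth)
    return SyntheticStudy(
        study=study,
        gene_coords=coords,
        gwas=gwas,
        interactions=graph,
        protein=protein,
        gene_sets=config.pathway_members(),
        truth=truth,
    )
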