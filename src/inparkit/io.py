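"""Plain-text readers and writers for the pipeline's file formats.

All tables are tab-separated. Gene sets use GMT (name, description,
genes...); gene coordinates use BED-style 0-based half-open columns;
interaction networks round-trip through a four-column edge list and are
exported as SIF for viewers.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexpr import ExpressionStudy
from .genesets import GeneSetCollection
from .inparnet import interaction_graph


def write_expression(study: ExpressionStudy, expr_path: str, annot_path: str) -> None:
    study.matrix.to_csv(expr_path, sep="\t")
    study.samples.to_csv(annot_path, sep="\t")


def read_expression(expr_path: str, annot_path: str, log2_scale: bool = True) -> ExpressionStudy:
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(annot_path, sep="\t", index_col=0, dtype=str)
    return ExpressionStudy(matrix=matrix, samples=samples, log2_scale=log2_scale)


def write_gmt(sets: dict[str, list[str]] | GeneSetCollection, path: str, description: str = "na") -> None:
    items = sets.items() if hasattr(sets, "items") else sets
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gmt(path: str, source: str = "custom") -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            sets[name] = {g for g in genes if g}
    return GeneSetCollection(sets, source=source)


def write_bed(coords: pd.DataFrame, path: str) -> None:
    coords[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
    )
    return df[["gene", "chrom", "start", "end"]]


def write_gwas(gwas: pd.DataFrame, path: str) -> None:
    gwas[["snp", "chrom", "pos", "p"]].to_csv(path, sep="\t", index=False)


def read_gwas(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp", "chrom", "pos", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"GWAS table must have columns {sorted(required)}")
    if df["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in GWAS table")
    return df


def write_edge_list(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\ttype\tevidence\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('type', 'direct')}\t{d.get('evidence', '')}\n")


def read_edge_list(path: str) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return interaction_graph(df)


def write_sif(edges: list[tuple[str, str]], path: str, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{relation}\t{v}\n")


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
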