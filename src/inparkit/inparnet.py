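"""Inter-pathway interaction network (INPAR-N) extraction and testing.

Given two pathway gene sets and a protein-interaction edge list, the
INPAR network is the set of genes incident to at least one *direct*
interaction whose endpoints fall one in each pathway, together with
those crossing edges. Its connectivity is tested against a
degree-aware permutation null (random node sets drawn within log2
degree bins), in the spirit of DAPPLE's degree-matched rewiring null.
A thin bipartite drug-target view maps the network onto pharmacology.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIRECT = "direct"
INDIRECT = "indirect"


def interaction_graph(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected interaction graph from an edge table.

    Columns: ``node_a, node_b, type`` (direct/indirect) and optionally
    ``evidence``. Self-loops are rejected; duplicate undirected edges
    keep the first occurrence (a direct record wins over indirect).
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = row.node_a, row.node_b
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        etype = getattr(row, "type", DIRECT)
        if etype not in (DIRECT, INDIRECT):
            raise ValueError(f"edge type must be direct/indirect, got {etype!r}")
        evidence = getattr(row, "evidence", "")
        if g.has_edge(a, b):
            if g[a][b]["type"] == INDIRECT and etype == DIRECT:
                g[a][b].update(type=DIRECT, evidence=evidence)
            continue
        g.add_edge(a, b, type=etype, evidence=evidence)
    return g


@dataclass
class InparNetwork:
    """Genes linking two pathways via direct crossing interactions."""

    members: set[str]
    crossing_edges: list[tuple[str, str]]
    pathway_labels: dict[str, str] = field(default_factory=dict)
    node_p: dict[str, float] = field(default_factory=dict)
    p_direct: float = np.nan
    p_indirect: float = np.nan


def extract_inpar_network(
    graph: nx.Graph,
    pathway_a: set[str],
    pathway_b: set[str],
) -> InparNetwork:
    """Members and edges of the inter-pathway interaction network.

    A direct edge qualifies when one endpoint lies in pathway A and the
    other in pathway B (a gene in both pathways may play either role).
    Indirect edges never qualify. The result is symmetric in (A, B);
    an empty network is a valid outcome.
    """
    if not pathway_a or not pathway_b:
        raise ValueError("pathways must be non-empty")
    crossing = []
    members: set[str] = set()
    for u, v, data in graph.edges(data=True):
        if data.get("type", DIRECT) != DIRECT:
            continue
        if (u in pathway_a and v in pathway_b) or (u in pathway_b and v in pathway_a):
            crossing.append((u, v))
            members.update((u, v))
    labels = {}
    for gene in members:
        in_a, in_b = gene in pathway_a, gene in pathway_b
        labels[gene] = "both" if (in_a and in_b) else ("A" if in_a else "B")
    crossing = sorted(tuple(sorted(e)) for e in crossing)
    return InparNetwork(members=members, crossing_edges=crossing, pathway_labels=labels)


def _degree_bins(degrees: np.ndarray, min_occupancy: int = 5) -> np.ndarray:
    """Assign nodes to log2-spaced degree bins, merging bins upward until
    every bin holds at least ``min_occupancy`` nodes."""
    bin_id = np.floor(np.log2(np.maximum(degrees, 1))).astype(int)
    # merge sparse bins into their lower neighbour
    uniq = np.unique(bin_id)
    mapping = {}
    carry: list[int] = []
    for b in uniq:
        carry.append(b)
        count = int(np.isin(bin_id, carry).sum())
        if count >= min_occupancy:
            for c in carry:
                mapping[c] = b
            carry = []
    if carry:  # leftover sparse top bins join the last full one
        target = max(mapping.values()) if mapping else carry[-1]
        if len(mapping) and int(np.isin(bin_id, carry).sum()) < min_occupancy:
            logger.info("sparse top degree bins widened into bin %d", target)
        for c in carry:
            mapping[c] = target
    return np.array([mapping[b] for b in bin_id])


def _direct_statistic(graph: nx.Graph, members: set[str]) -> int:
    return sum(
        1
        for u, v, d in graph.subgraph(members).edges(data=True)
        if d.get("type", DIRECT) == DIRECT
    )


def _indirect_statistic(graph: nx.Graph, members: set[str]) -> int:
    """Member pairs sharing at least one non-member neighbour."""
    mem = sorted(members)
    neigh = {m: set(graph.neighbors(m)) - members for m in mem if m in graph}
    count = 0
    for i, a in enumerate(mem):
        na = neigh.get(a, set())
        if not na:
            continue
        for b in mem[i + 1:]:
            if na & neigh.get(b, set()):
                count += 1
    return count


def connectivity_enrichment(
    members: set[str],
    background: nx.Graph,
    n_perm: int = 1000,
    seed: int | None = None,
) -> InparNetwork:
    """Degree-aware permutation test of network connectivity.

    The direct statistic is the number of direct edges among members;
    the indirect statistic counts member pairs sharing a non-member
    neighbour. Null sets of equal size are drawn by replacing each
    member with a uniform draw from its log2 degree bin, so the null
    preserves the degree profile. p-values use the add-one correction
    (b+1)/(n_perm+1). Per-node p compares each member's within-member
    direct degree to the same node's degree into the sampled null sets.
    """
    missing = members - set(background.nodes)
    if missing:
        raise ValueError(f"members absent from background graph: {sorted(missing)[:10]}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful permutation null")
    members = set(members)
    nodes = np.array(sorted(background.nodes), dtype=object)
    degrees = np.array([background.degree(n) for n in nodes])
    bins = _degree_bins(degrees)
    by_bin: dict[int, np.ndarray] = {b: nodes[bins == b] for b in np.unique(bins)}
    node_bin = dict(zip(nodes, bins))

    obs_direct = _direct_statistic(background, members)
    obs_indirect = _indirect_statistic(background, members)
    mem_sorted = sorted(members)
    obs_node_deg = {
        m: sum(
            1
            for nb in background.neighbors(m)
            if nb in members and background[m][nb].get("type", DIRECT) == DIRECT
        )
        for m in mem_sorted
    }

    rng = np.random.default_rng(seed)
    ge_direct = 0
    ge_indirect = 0
    node_ge = dict.fromkeys(mem_sorted, 0)
    m = len(members)
    for _ in range(n_perm):
        # degree-binned resample of the member set, without replacement
        draw: set[str] = set()
        need = Counter(node_bin[x] for x in mem_sorted)
        for b, cnt in need.items():
            pool = by_bin[b]
            take = rng.choice(len(pool), size=min(cnt, len(pool)), replace=False)
            draw.update(pool[take])
        ge_direct += _direct_statistic(background, draw) >= obs_direct
        ge_indirect += _indirect_statistic(background, draw) >= obs_indirect
        # per-node null: each member's direct degree into the sampled set
        for mname in mem_sorted:
            others = draw - {mname}
            d = sum(
                1
                for nb in background.neighbors(mname)
                if nb in others and background[mname][nb].get("type", DIRECT) == DIRECT
            )
            node_ge[mname] += d >= obs_node_deg[mname]

    net = InparNetwork(
        members=members,
        crossing_edges=[],
        p_direct=(ge_direct + 1) / (n_perm + 1),
        p_indirect=(ge_indirect + 1) / (n_perm + 1),
        node_p={mname: (node_ge[mname] + 1) / (n_perm + 1) for mname in mem_sorted},
    )
    if m <= 1:
        net.p_direct = net.p_indirect = 1.0
    return net


def drug_bipartite(
    members: set[str],
    drug_targets: pd.DataFrame,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite drug-gene graph over network members with per-drug
    consensus physiological effect.

    ``drug_targets`` needs columns ``drug, gene, effect``. Only member
    genes with at least one targeting drug enter the graph; untargeted
    members are returned in the companion table. The consensus effect
    is the modal effect tag of a drug's rows; ties are ``ambiguous``.
    """
    required = {"drug", "gene", "effect"}
    if not required <= set(drug_targets.columns):
        raise ValueError(f"drug table must have columns {sorted(required)}")
    hits = drug_targets[drug_targets["gene"].isin(members)]
    g = nx.Graph()
    for row in hits.itertuples(index=False):
        g.add_node(row.drug, bipartite="drug")
        g.add_node(row.gene, bipartite="gene")
        g.add_edge(row.drug, row.gene, effect=row.effect)
    consensus_rows = []
    for drug, grp in hits.groupby("drug"):
        counts = Counter(grp["effect"])
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            effect = "ambiguous"
        else:
            effect = top[0][0]
        consensus_rows.append((drug, int(grp["gene"].nunique()), effect))
    consensus = pd.DataFrame(
        consensus_rows, columns=["drug", "n_targets", "consensus_effect"]
    ).set_index("drug")
    untargeted = sorted(members - set(hits["gene"]))
    consensus.attrs["untargeted_members"] = untargeted
    return g, consensus
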