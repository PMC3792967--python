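"""Co-enrichment of pathways across expression and GWAS evidence.

A pathway significant in CD4+ T cell expression response *and* in GWAS
of the systemic phenotype is a candidate causal pathway. The two
enrichment p-values are combined under a global null (all component
nulls must be false), either assuming independence,
``1 - prod(1 - p_k)``, or conservatively via the Sidak-corrected
maximum, ``1 - (1 - max p)^K``. Pathways are then screened by Pareto
efficiency in the (expression p, GWAS p) objective space and ranked by
global p with the expression odds ratio as effect-size tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoEnrichmentRecord:
    """Joint expression/GWAS enrichment evidence for one pathway."""

    name: str
    p_expr: float  # max of GSEA and hypergeometric p
    p_gwas: float
    p_global: float = np.nan
    or_expr: float = np.nan
    pareto: bool = False
    selected: bool = False


def combine_global_p(p_values: list[float] | np.ndarray, method: str = "sidak_max") -> float:
    """Combine K p-values under the global null that all K nulls hold.

    ``independence``: 1 - prod(1 - p_k). ``sidak_max``:
    1 - (1 - max p)^K, conservative under dependence.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if method == "independence":
        return float(1.0 - np.prod(1.0 - p))
    if method == "sidak_max":
        return float(1.0 - (1.0 - p.max()) ** p.size)
    raise ValueError(f"unknown method {method!r}")


def pareto_front(
    points: np.ndarray | list[tuple[float, float]],
    bound: float | None = None,
) -> np.ndarray:
    """Non-domination flags for points minimised in both coordinates.

    Point i is efficient iff no other point is <= in both coordinates
    with < in at least one. Duplicate points do not dominate each other.
    With ``bound`` given, efficiency additionally requires both
    coordinates <= bound.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    flags = np.ones(n, dtype=bool)
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # by x then y
    best_y = np.inf
    # sweep in x order: a point is dominated iff some strictly better-or-equal
    # earlier point has y <= its y with at least one strict inequality
    for rank, i in enumerate(order):
        x, y = pts[i]
        dominated = False
        if y > best_y:
            dominated = True
        elif y == best_y:
            # dominated only if a previous point with the same y had smaller x
            for j in order[:rank]:
                if pts[j, 1] == y and pts[j, 0] < x:
                    dominated = True
                    break
        flags[i] = not dominated
        best_y = min(best_y, y)
    if bound is not None:
        flags &= (pts[:, 0] <= bound) & (pts[:, 1] <= bound)
    return flags


def make_records(
    expr_enrich: pd.DataFrame,
    gwas_enrich: pd.DataFrame,
    method: str = "sidak_max",
) -> list[CoEnrichmentRecord]:
    """Join expression-side and GWAS-side enrichment tables by pathway.

    ``expr_enrich`` must carry columns ``p_hyper, p_gsea, odds_ratio``
    indexed by set name; ``gwas_enrich`` carries ``p``. The expression
    objective is the maximum of the GSEA and hypergeometric p-values.
    """
    common = expr_enrich.index.intersection(gwas_enrich.index)
    records = []
    for name in common:
        p_expr = float(np.nanmax([expr_enrich.loc[name, "p_hyper"], expr_enrich.loc[name, "p_gsea"]]))
        p_gwas = float(gwas_enrich.loc[name, "p"])
        rec = CoEnrichmentRecord(
            name=name,
            p_expr=p_expr,
            p_gwas=p_gwas,
            p_global=combine_global_p([p_expr, p_gwas], method=method),
            or_expr=float(expr_enrich.loc[name, "odds_ratio"]),
        )
        records.append(rec)
    return records


def prioritize_pathways(
    records: list[CoEnrichmentRecord],
    bound: float | None = 0.05,
) -> list[CoEnrichmentRecord]:
    """Flag Pareto-efficient pathways within the significance bound and
    rank them by global p (ascending), ties broken by expression odds
    ratio (descending); the top record gets ``selected=True``.

    Returns the efficient records in rank order (empty when none falls
    within the bound).
    """
    if not records:
        return []
    pts = np.array([[r.p_expr, r.p_gwas] for r in records])
    flags = pareto_front(pts, bound=bound)
    for rec, f in zip(records, flags):
        rec.pareto = bool(f)
        rec.selected = False
    efficient = [r for r in records if r.pareto]
    efficient.sort(key=lambda r: (r.p_global, -r.or_expr))
    if efficient:
        efficient[0].selected = True
    return efficient


def records_to_frame(records: list[CoEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.name for r in records],
            "p_expr": [r.p_expr for r in records],
            "p_gwas": [r.p_gwas for r in records],
            "p_global": [r.p_global for r in records],
            "or_expr": [r.or_expr for r in records],
            "pareto": [r.pareto for r in records],
            "selected": [r.selected for r in records],
        }
    ).set_index("pathway")


def plot_objective_space(records: list[CoEnrichmentRecord], path: str) -> None:
    """Scatter of -log10 p_expr vs -log10 p_gwas with the Pareto front marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x = [-np.log10(max(r.p_expr, 1e-300)) for r in records]
    y = [-np.log10(max(r.p_gwas, 1e-300)) for r in records]
    sizes = [20 + 10 * max(r.or_expr, 0) for r in records]
    colors = ["tab:red" if r.pareto else "tab:gray" for r in records]
    ax.scatter(x, y, s=sizes, c=colors, alpha=0.7)
    for r, xi, yi in zip(records, x, y):
        if r.pareto:
            ax.annotate(r.name, (xi, yi), fontsize=7)
    ax.set_xlabel(r"$-\log_{10} p$ (expression enrichment)")
    ax.set_ylabel(r"$-\log_{10} p$ (GWAS enrichment)")
    ax.set_title("Pathway co-enrichment objective space")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
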