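"""Correlation-based coordination statistics.

Two questions are addressed. First, is a gene set internally more
co-expressed than background (correlation enrichment: within-set |rho|
vs set-to-rest |rho|, Welch t, set-membership permutation, and ROC
AUC)? The same machinery measures enrichment of correlation against a
response vector such as supernatant IL-13 protein. Second, is the
coordination *dysregulated* in disease: per gene pair, the Spearman
correlation difference between case and control arms is tested with
Fisher's z, and the count of nominally significant differences is
compared to the N*alpha expectation with an exact two-sided binomial
test (minimum-likelihood two-sided definition).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RHO_CLIP = 1.0 - 1e-10


@dataclass
class CorrelationEnrichment:
    """Correlation-enrichment summary of one gene set."""

    name: str
    target: str  # "self" or the response-vector name
    mean_abs_rho_set: float
    mean_abs_rho_null: float
    p_t: float
    p_perm: float
    auc: float
    auc_p: float
    auc_ci_low: float
    auc_ci_high: float


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix of rows of x (genes x samples)."""
    ranks = stats.rankdata(x, axis=1)
    return np.corrcoef(ranks)


def _drop_constant(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant genes", int(constant.sum()))
        matrix = matrix.loc[~constant]
    return matrix


def _auc_rank_sum(in_group: np.ndarray, null_group: np.ndarray) -> tuple[float, float, float, float]:
    """AUC = P(in-group score > null score) via the Mann-Whitney U
    statistic, with its normal-approximation p and 95% CI (Hanley-McNeil)."""
    n1, n2 = len(in_group), len(null_group)
    res = stats.mannwhitneyu(in_group, null_group, alternative="two-sided")
    auc = float(res.statistic) / (n1 * n2)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return auc, float(res.pvalue), max(auc - half, 0.0), min(auc + half, 1.0)


def _group_scores(
    corr: np.ndarray, in_set: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Within-set |rho| and set-to-rest |rho| from a full correlation matrix."""
    a = np.abs(corr)
    iu = np.triu_indices_from(a, k=1)
    pair_in = in_set[iu[0]] & in_set[iu[1]]
    pair_cross = in_set[iu[0]] ^ in_set[iu[1]]
    return a[iu][pair_in], a[iu][pair_cross]


def correlation_enrichment(
    matrix: pd.DataFrame,
    gene_set: set[str],
    target: str | pd.Series = "self",
    n_perm: int = 1000,
    seed: int | None = None,
    name: str = "",
) -> CorrelationEnrichment:
    """Correlation enrichment of a gene set, against itself or a response.

    ``target="self"``: the in-group scores are absolute Spearman
    correlations over all within-set gene pairs, the null group over all
    set x rest pairs. A response ``pd.Series`` (indexed by sample):
    in-group = |rho| of set genes vs the response, null = |rho| of the
    remaining genes vs the response. Welch t compares the group means;
    the permutation p resamples set membership ``n_perm`` times and
    compares the mean in-group |rho|; AUC is the rank-sum probability
    that an in-group score exceeds a null score.
    """
    matrix = _drop_constant(matrix)
    if matrix.shape[1] < 3:
        raise ValueError("need >=3 samples for correlation analysis")
    genes = matrix.index
    in_set = np.asarray(genes.isin(gene_set))
    K = int(in_set.sum())
    self_target = isinstance(target, str) and target == "self"
    if self_target and K < 2:
        raise ValueError("self-target enrichment needs >=2 set genes in the matrix")
    if not self_target and K < 1:
        raise ValueError("no set genes present in the matrix")

    rng = np.random.default_rng(seed)
    if self_target:
        corr = _spearman_matrix(matrix.to_numpy(float))
        in_scores, null_scores = _group_scores(corr, in_set)

        def mean_in(mask: np.ndarray) -> float:
            s, _ = _group_scores(corr, mask)
            return float(s.mean())

        target_name = "self"
    else:
        y = target.loc[matrix.columns].to_numpy(float)
        yr = stats.rankdata(y)
        ranks = stats.rankdata(matrix.to_numpy(float), axis=1)
        yc = yr - yr.mean()
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        rho = (rc @ yc) / (
            np.sqrt((rc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
        )
        scores = np.abs(rho)
        in_scores, null_scores = scores[in_set], scores[~in_set]

        def mean_in(mask: np.ndarray) -> float:
            return float(scores[mask].mean())

        target_name = str(target.name or "response")

    t_res = stats.ttest_ind(in_scores, null_scores, equal_var=False)
    observed = float(in_scores.mean())
    ge = 0
    for _ in range(n_perm):
        mask = np.zeros(len(genes), dtype=bool)
        mask[rng.choice(len(genes), size=K, replace=False)] = True
        ge += mean_in(mask) >= observed
    p_perm = (ge + 1) / (n_perm + 1)
    auc, auc_p, lo, hi = _auc_rank_sum(in_scores, null_scores)
    return CorrelationEnrichment(
        name=name,
        target=target_name,
        mean_abs_rho_set=observed,
        mean_abs_rho_null=float(null_scores.mean()),
        p_t=float(t_res.pvalue),
        p_perm=float(p_perm),
        auc=auc,
        auc_p=auc_p,
        auc_ci_low=lo,
        auc_ci_high=hi,
    )


def fisher_z_difference(rho1: float, rho2: float, n1: int, n2: int) -> tuple[float, float]:
    """Two-sided test of equality of two correlations via Fisher's z.

    z = (atanh rho1 - atanh rho2) / sqrt(1/(n1-3) + 1/(n2-3)); |rho| is
    clipped just inside 1 to keep atanh finite.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each arm needs more than 3 samples for Fisher's z")
    r1 = float(np.clip(rho1, -RHO_CLIP, RHO_CLIP))
    r2 = float(np.clip(rho2, -RHO_CLIP, RHO_CLIP))
    if r1 != rho1 or r2 != rho2:
        logger.warning("|rho| at 1 clipped to %.1e short of unity", 1 - RHO_CLIP)
    z = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def correlation_difference_table(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair case/control Spearman correlation difference p-values.

    ``cases`` and ``controls`` are genes x samples matrices of the two
    arms. Pairs whose correlation is undefined in either arm (constant
    ranks) are skipped and logged. Columns of the result:
    ``gene_a, gene_b, rho_cases, rho_controls, z, p``.
    """
    n1, n2 = cases.shape[1], controls.shape[1]
    if n1 < 4 or n2 < 4:
        raise ValueError("each arm needs >=4 samples")
    rows = []
    skipped = 0
    for a, b in pairs:
        xa, ya = cases.loc[a].to_numpy(float), cases.loc[b].to_numpy(float)
        xb, yb = controls.loc[a].to_numpy(float), controls.loc[b].to_numpy(float)
        r1 = stats.spearmanr(xa, ya).statistic
        r2 = stats.spearmanr(xb, yb).statistic
        if not (np.isfinite(r1) and np.isfinite(r2)):
            skipped += 1
            continue
        z, p = fisher_z_difference(r1, r2, n1, n2)
        rows.append((a, b, float(r1), float(r2), z, p))
    if skipped:
        logger.warning("%d gene pairs skipped (undefined correlation)", skipped)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho_cases", "rho_controls", "z", "p"])


def all_pairs(genes: list[str]) -> list[tuple[str, str]]:
    return list(combinations(genes, 2))


def cross_pairs(genes_a: list[str], genes_b: list[str]) -> list[tuple[str, str]]:
    """Pairs crossing two gene sets, each unordered pair counted once and
    within-overlap pairs excluded."""
    seen = set()
    out = []
    for a in genes_a:
        for b in genes_b:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CoordinationResult:
    """Observed vs expected nominally significant correlation differences."""

    name: str
    condition: str
    n_pairs: int
    observed: int
    expected: int
    p_binom: float
    detail: pd.DataFrame | None = None


def dysregulation_summary(
    pair_pvalues: np.ndarray | list[float],
    alpha: float = 0.05,
    name: str = "",
    condition: str = "",
) -> CoordinationResult:
    """Binomial excess test of significant correlation differences.

    ``observed`` counts pair p-values strictly below alpha; ``expected``
    is N*alpha rounded half-up (for reporting only); the p-value is the
    exact two-sided binomial test of the raw observed count against
    success probability alpha.
    """
    p = np.asarray(pair_pvalues, float)
    if p.size < 1:
        raise ValueError("need at least one pair p-value")
    n = int(p.size)
    observed = int((p < alpha).sum())
    expected = round_half_up(n * alpha)
    p_binom = float(stats.binomtest(observed, n, alpha).pvalue)
    return CoordinationResult(
        name=name, condition=condition, n_pairs=n,
        observed=observed, expected=expected, p_binom=p_binom,
    )


def sign_test_superiority(comparisons: list[tuple[float, float]]) -> float:
    """One-sided sign test that the first member of each pair is larger.

    Exact ties are dropped with a warning; p = P(X >= successes) for
    X ~ Binomial(n, 1/2).
    """
    kept = [(a, b) for a, b in comparisons if a != b]
    dropped = len(comparisons) - len(kept)
    if dropped:
        logger.warning("%d tied comparisons dropped from sign test", dropped)
    if not kept:
        raise ValueError("no informative comparisons after tie removal")
    successes = sum(a > b for a, b in kept)
    return float(stats.binom.sf(successes - 1, len(kept), 0.5))
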