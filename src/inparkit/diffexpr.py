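"""Per-gene differential expression and cross-study meta-analysis.

The central quantity is the log2 ratio of group means between two arms of
a case/control x allergen/diluent culture design, tested with a Welch
t-test (optionally calibrated by label permutation) and pooled across
studies by fixed-effect inverse-variance meta-analysis of the log ratios.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ARM_COLUMNS = ("group", "challenge")


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with per-sample annotations.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Expression intensities, genes as rows, samples as columns.
        Log2 scale by convention (``log2_scale=True``).
    samples : pandas.DataFrame
        One row per sample (index = sample id) with columns ``group``
        (``case``/``control``), ``challenge`` (``allergen``/``diluent``)
        and optionally ``pairing`` (subject id for paired cultures; the
        analysis treats arms as unpaired, the id is carried for
        bookkeeping only).
    log2_scale : bool
        Whether ``matrix`` holds log2 intensities (default) or
        linear-scale intensities.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    log2_scale: bool = True

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dup)[:5]}")
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
        for col in ARM_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation lacks column {col!r}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def arm_samples(self, group: str, challenge: str) -> list[str]:
        """Sample ids belonging to one arm of the 2x2 design."""
        ann = self.samples.loc[list(self.matrix.columns)]
        mask = (ann["group"] == group) & (ann["challenge"] == challenge)
        return list(ann.index[mask])

    def arm_matrix(self, group: str, challenge: str) -> pd.DataFrame:
        return self.matrix[self.arm_samples(group, challenge)]


@dataclass
class DEResult:
    """Differential-expression summary for one gene."""

    gene: str
    log2_ratio: float
    se: float
    stat: float
    p: float
    q: float = np.nan
    p_perm: float = np.nan


_CONTRAST_RE = re.compile(r"^(\w+)_(\w+)-vs-(\w+)_(\w+)$")


def parse_contrast(contrast: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """Parse ``"case_allergen-vs-case_diluent"`` into two (group, challenge) arms."""
    m = _CONTRAST_RE.match(contrast)
    if m is None:
        raise ValueError(
            f"contrast {contrast!r} not of the form 'group_challenge-vs-group_challenge'"
        )
    return (m.group(1), m.group(2)), (m.group(3), m.group(4))


def _welch(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch statistics for rows of two (genes x samples) arrays.

    Returns (difference of means, standard error, Welch-Satterthwaite df).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    a, b = v1 / n1, v2 / n2
    se = np.sqrt(a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    return m1 - m2, se, df


def differential_expression(
    study: ExpressionStudy,
    contrast: str | tuple[tuple[str, str], tuple[str, str]],
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene log2 ratio of arm means with Welch t-test and BH q-values.

    For a log2-scale matrix the log2 ratio of means is the difference of
    arm means; for a linear-scale matrix it is log2(mean1/mean2) with a
    delta-method standard error. ``n_perm > 0`` adds a label-permutation
    p-value obtained by shuffling arm membership and recomputing t.

    Returns a DataFrame indexed by gene with columns
    ``log2_ratio, se, stat, p, p_perm, q``.
    """
    if isinstance(contrast, str):
        arm1, arm2 = parse_contrast(contrast)
    else:
        arm1, arm2 = contrast
    s1 = study.arm_samples(*arm1)
    s2 = study.arm_samples(*arm2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(
            f"each contrast arm needs >=2 samples, got {len(s1)} vs {len(s2)} "
            f"for {arm1} vs {arm2}"
        )
    x1 = study.matrix[s1].to_numpy(float)
    x2 = study.matrix[s2].to_numpy(float)

    if study.log2_scale:
        lr, se, df = _welch(x1, x2)
        stat = np.divide(lr, se, out=np.zeros_like(lr), where=se > 0)
    else:
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        bad = (m1 <= 0) | (m2 <= 0)
        if bad.any():
            names = list(study.genes[bad][:5])
            raise ValueError(f"non-positive arm mean for genes {names}; cannot take log")
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        lr = np.log2(m1 / m2)
        # delta method: var(log2 m) = var(m) / (m ln2)^2
        se = np.sqrt(v1 / (x1.shape[1] * m1**2) + v2 / (x2.shape[1] * m2**2)) / np.log(2)
        _, _, df = _welch(x1, x2)
        stat = np.divide(lr, se, out=np.zeros_like(lr), where=se > 0)

    p = 2.0 * stats.t.sf(np.abs(stat), df)
    p = np.clip(p, 0.0, 1.0)

    p_perm = np.full(lr.shape, np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x1, x2], axis=1)
        n1 = x1.shape[1]
        exceed = np.zeros(lr.shape, dtype=np.int64)
        abs_obs = np.abs(stat)
        for _ in range(n_perm):
            idx = rng.permutation(pooled.shape[1])
            y1, y2 = pooled[:, idx[:n1]], pooled[:, idx[n1:]]
            d, s, _ = _welch(y1, y2)
            t_null = np.divide(d, s, out=np.zeros_like(d), where=s > 0)
            exceed += np.abs(t_null) >= abs_obs
        p_perm = (exceed + 1) / (n_perm + 1)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_ratio": lr,
            "se": se,
            "stat": stat,
            "p": p,
            "p_perm": p_perm,
            "q": q,
        },
        index=study.genes.rename("gene"),
    )


def meta_analyze_logratios(results_by_study: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance pooling of per-gene log2 ratios.

    Each input frame must be indexed by gene with columns ``log2_ratio``
    and ``se``. Genes absent from any study are excluded (inner join)
    and logged. Pooled estimate = sum(w_i * est_i) / sum(w_i) with
    w_i = 1/se_i^2; pooled SE = sum(w_i)^(-1/2); two-sided normal p.
    """
    if len(results_by_study) < 2:
        raise ValueError("meta-analysis requires >=2 studies")
    common = results_by_study[0].index
    union = results_by_study[0].index
    for df in results_by_study[1:]:
        common = common.intersection(df.index)
        union = union.union(df.index)
    dropped = union.difference(common)
    if len(dropped):
        logger.info("meta-analysis: %d genes absent from some study excluded", len(dropped))
    ests = np.column_stack([df.loc[common, "log2_ratio"].to_numpy(float) for df in results_by_study])
    ses = np.column_stack([df.loc[common, "se"].to_numpy(float) for df in results_by_study])
    if (ses <= 0).any():
        raise ValueError("non-positive standard error in meta-analysis input")
    w = 1.0 / ses**2
    pooled = (w * ests).sum(axis=1) / w.sum(axis=1)
    pooled_se = w.sum(axis=1) ** -0.5
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"log2_ratio": pooled, "se": pooled_se, "stat": z, "p": p},
        index=common.rename("gene"),
    )


def is_reproducible(
    meta_p: float,
    discovery_p: float,
    n_tests: int,
    alpha: float = 0.05,
    replication_p: float | None = None,
) -> bool:
    """Reproducibility decision for a meta-analysed gene.

    A gene is reproducibly differentially expressed when its
    meta-analysis p-value is strictly smaller than both the discovery
    p-value and the Bonferroni-corrected family level ``alpha/n_tests``.
    ``replication_p`` is accepted for bookkeeping symmetry but does not
    enter the rule.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    for name, val in (("meta_p", meta_p), ("discovery_p", discovery_p)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0, 1]")
    return meta_p < discovery_p and meta_p < alpha / n_tests
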