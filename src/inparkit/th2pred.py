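"""Predictive regression of Th2 differentiation markers.

The gene expression of a candidate network is used to predict (i) a
single response such as supernatant IL-13 protein, scored by the
cross-validated predictive fit Q^2 = 1 - PRESS/TSS, and (ii) the Th2
cytokine panel jointly, scored by Wilks' Lambda = det(E)/det(E+H) with
1 - Lambda playing the role of a multivariate R^2, both in-sample and
from cross-validated residuals. Permutation of the response provides a
distribution-free check of the cross-validated statistics, and the
standardized coefficient matrix is bi-clustered with bootstrap support
values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.model_selection import KFold, LeaveOneOut

logger = logging.getLogger(__name__)

RIDGE_FALLBACK = 1e-3


@dataclass
class RegressionReport:
    """Fit and predictive-power summary of a (multi)variate regression."""

    responses: list[str]
    predictors: list[str]
    r2_y: float
    q2_y: float
    model_p: float
    q2_p: float
    coef: pd.DataFrame | None = None  # standardized, responses x predictors


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def _ols_fit(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with a small ridge penalty when the
    design is rank-deficient (predictors >= training samples)."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    if p + 1 >= n:
        logger.info("design with %d predictors and %d samples: ridge fallback", p, n)
        reg = RIDGE_FALLBACK * np.eye(p + 1)
        reg[0, 0] = 0.0
        return np.linalg.solve(Xd.T @ Xd + reg, Xd.T @ Y)
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    return beta


def _folds(n: int, k_folds: int | str, seed: int | None):
    if k_folds == "loo":
        return list(LeaveOneOut().split(np.arange(n)))
    k = int(k_folds)
    if n < k:
        raise ValueError(f"{n} samples cannot be split into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _press_tss(X: np.ndarray, y: np.ndarray, splits) -> tuple[float, float]:
    """Cross-validated PRESS and TSS (TSS about the training-fold means)."""
    press = tss = 0.0
    for train, test in splits:
        Xtr, Xte = _standardize(X[train], X[test])
        beta = _ols_fit(Xtr, y[train])
        pred = np.column_stack([np.ones(len(test)), Xte]) @ beta
        press += float(((y[test] - pred) ** 2).sum())
        tss += float(((y[test] - y[train].mean()) ** 2).sum())
    return press, tss


def crossval_q2_regression(
    X: pd.DataFrame,
    y: pd.Series,
    k_folds: int | str = 7,
    n_perm: int = 1000,
    seed: int | None = None,
) -> RegressionReport:
    """Cross-validated Q^2 of an OLS regression with permutation test.

    ``X`` is samples x predictors, ``y`` the response over the same
    samples. Predictors are standardized inside each training fold (the
    scaler never sees the held-out samples). Q^2 = 1 - PRESS/TSS with
    the TSS about training-fold means; the model p-value is the overall
    F test of the full-data fit; ``q2_p`` is the add-one-corrected
    fraction of ``n_perm`` response permutations reaching the observed
    Q^2.
    """
    Xa = X.to_numpy(float)
    ya = y.loc[X.index].to_numpy(float)
    n, p = Xa.shape
    splits = _folds(n, k_folds, seed)
    press, tss = _press_tss(Xa, ya, splits)
    q2 = 1.0 - press / tss

    # in-sample fit and F test on the full data
    Xs, _ = _standardize(Xa, Xa)
    beta = _ols_fit(Xs, ya)
    resid = ya - np.column_stack([np.ones(n), Xs]) @ beta
    rss = float((resid**2).sum())
    tss_in = float(((ya - ya.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss_in
    df_model, df_resid = p, n - p - 1
    if df_resid > 0 and rss > 0:
        f = (tss_in - rss) / df_model / (rss / df_resid)
        model_p = float(stats.f.sf(f, df_model, df_resid))
    else:
        model_p = np.nan

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        yp = rng.permutation(ya)
        press_p, tss_p = _press_tss(Xa, yp, splits)
        ge += (1.0 - press_p / tss_p) >= q2
    q2_p = (ge + 1) / (n_perm + 1)

    coef = pd.DataFrame(
        [beta[1:] * 1.0], index=[str(y.name or "response")], columns=list(X.columns)
    )
    return RegressionReport(
        responses=[str(y.name or "response")],
        predictors=list(X.columns),
        r2_y=float(r2),
        q2_y=float(q2),
        model_p=model_p,
        q2_p=float(q2_p),
        coef=coef,
    )


def _wilks_lambda(E: np.ndarray, H: np.ndarray) -> float:
    """Lambda = det(E)/det(E+H) computed stably via eigenvalues of
    solve(E+H, E)."""
    total = E + H
    sign, logdet_t = np.linalg.slogdet(total)
    if sign <= 0:
        raise ValueError("singular residual covariance; reduce responses or regularize")
    sign_e, logdet_e = np.linalg.slogdet(E)
    if sign_e <= 0:
        raise ValueError("singular residual covariance; reduce responses or regularize")
    return float(np.exp(logdet_e - logdet_t))


def _rao_f_p(lam: float, n: int, p: int, q: int) -> float:
    """Rao's F approximation to the Wilks Lambda null distribution.

    p = number of predictors (hypothesis df), q = number of responses,
    n = samples; the error df is n - p - 1.
    """
    ve = n - p - 1
    s2 = p**2 * q**2 - 4
    s = math.sqrt(s2 / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = s * (ve - (q - p + 1) / 2) - (p * q - 2) / 2
    if df2 <= 0:
        return float("nan")
    lam_s = lam ** (1.0 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    return float(stats.f.sf(f, df1, df2))


def multivariate_wilks(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    k_folds: int | str = 7,
    n_perm: int = 1000,
    seed: int | None = None,
) -> RegressionReport:
    """Multivariate regression scored by Wilks' Lambda, in and out of sample.

    In-sample: Lambda = det(E)/det(E+H) from the multivariate linear
    model of Y on standardized X, reported as 1 - Lambda with Rao's F
    p-value. Out of sample: E is replaced by the SSCP of cross-validated
    residuals and E+H by the SSCP of cross-validated deviations from
    training-fold response means; ``q2_y`` reports 1 - Lambda_oos, with
    an add-one-corrected response-permutation p-value.
    """
    if Y.shape[1] < 2:
        raise ValueError("multivariate regression needs >=2 responses")
    Xa = X.to_numpy(float)
    Ya = Y.loc[X.index].to_numpy(float)
    n, p = Xa.shape
    q = Ya.shape[1]
    if n <= q:
        raise ValueError("need more samples than responses")

    def insample_lambda(Yv: np.ndarray) -> tuple[float, np.ndarray]:
        Xs, _ = _standardize(Xa, Xa)
        beta = _ols_fit(Xs, Yv)
        fitted = np.column_stack([np.ones(n), Xs]) @ beta
        resid = Yv - fitted
        centered = Yv - Yv.mean(axis=0)
        E = resid.T @ resid
        H = centered.T @ centered - E
        return _wilks_lambda(E, H), beta

    def oos_lambda(Yv: np.ndarray, splits) -> float:
        E = np.zeros((q, q))
        T = np.zeros((q, q))
        for train, test in splits:
            Xtr, Xte = _standardize(Xa[train], Xa[test])
            beta = _ols_fit(Xtr, Yv[train])
            pred = np.column_stack([np.ones(len(test)), Xte]) @ beta
            r = Yv[test] - pred
            d = Yv[test] - Yv[train].mean(axis=0)
            E += r.T @ r
            T += d.T @ d
        sign, _ = np.linalg.slogdet(T)
        if sign <= 0:
            raise ValueError("degenerate held-out response covariance")
        return _wilks_lambda(E, T - E) if _psd_ok(T - E) else float(
            np.exp(np.linalg.slogdet(E)[1] - np.linalg.slogdet(T)[1])
        )

    def _psd_ok(M: np.ndarray) -> bool:
        return bool(np.all(np.linalg.eigvalsh((M + M.T) / 2) > -1e-9))

    splits = _folds(n, k_folds, seed)
    lam, beta = insample_lambda(Ya)
    lam_oos = oos_lambda(Ya, splits)
    model_p = _rao_f_p(lam, n, p, q)

    rng = np.random.default_rng(seed)
    ge = 0
    obs = 1.0 - lam_oos
    for _ in range(n_perm):
        Yp = Ya[rng.permutation(n)]
        try:
            ge += (1.0 - oos_lambda(Yp, splits)) >= obs
        except ValueError:
            ge += 0
    q2_p = (ge + 1) / (n_perm + 1)

    # standardized coefficients: responses x predictors
    y_sd = Ya.std(axis=0, ddof=1)
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    coef = pd.DataFrame(
        (beta[1:] / y_sd).T, index=list(Y.columns), columns=list(X.columns)
    )
    return RegressionReport(
        responses=list(Y.columns),
        predictors=list(X.columns),
        r2_y=float(1.0 - lam),
        q2_y=float(1.0 - lam_oos),
        model_p=model_p,
        q2_p=float(q2_p),
        coef=coef,
    )


def _subtree_leafsets(link: np.ndarray, labels: list[str]) -> set[frozenset]:
    """All internal-node leaf sets of a linkage tree (size >= 2, < all)."""
    n = len(labels)
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for i, (a, b, *_rest) in enumerate(link):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + i] = merged
        if 1 < len(merged) < n:
            out.add(merged)
    return out


def _corr_linkage(mat: np.ndarray) -> np.ndarray:
    """Average-linkage tree on correlation distance between rows."""
    c = np.corrcoef(mat)
    c = np.nan_to_num(c, nan=0.0)
    d = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def coefficient_clustering(
    coef: pd.DataFrame,
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_boot: int = 200,
    seed: int | None = None,
    support_threshold: float = 0.95,
) -> dict[str, object]:
    """Bi-clustering of the standardized coefficient matrix with
    bootstrap cluster support.

    Rows (responses) and columns (predictors) are clustered by
    correlation distance with average linkage. Support of each subtree
    cluster is the fraction of ``n_boot`` sample-bootstrap refits of the
    multivariate regression in which the same leaf set reappears as a
    subtree; clusters at support >= ``support_threshold`` are flagged.
    """
    if coef.shape[0] < 3 or coef.shape[1] < 3:
        logger.warning("coefficient matrix below 3x3; clustering skipped")
        return {"row_linkage": None, "col_linkage": None, "row_support": {}, "col_support": {}}
    rows = list(coef.index)
    cols = list(coef.columns)
    row_link = _corr_linkage(coef.to_numpy(float))
    col_link = _corr_linkage(coef.to_numpy(float).T)
    row_ref = _subtree_leafsets(row_link, rows)
    col_ref = _subtree_leafsets(col_link, cols)
    row_hits = dict.fromkeys(row_ref, 0)
    col_hits = dict.fromkeys(col_ref, 0)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    done = 0
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        Xb = X.iloc[idx]
        Yb = Y.iloc[idx]
        Xs, _ = _standardize(Xb.to_numpy(float), Xb.to_numpy(float))
        try:
            beta = _ols_fit(Xs, Yb.to_numpy(float))
        except np.linalg.LinAlgError:
            continue
        y_sd = Yb.to_numpy(float).std(axis=0, ddof=1)
        y_sd = np.where(y_sd > 0, y_sd, 1.0)
        cb = (beta[1:] / y_sd).T
        for leafset in _subtree_leafsets(_corr_linkage(cb), rows):
            if leafset in row_hits:
                row_hits[leafset] += 1
        for leafset in _subtree_leafsets(_corr_linkage(cb.T), cols):
            if leafset in col_hits:
                col_hits[leafset] += 1
        done += 1
    denom = max(done, 1)
    row_support = {s: h / denom for s, h in row_hits.items()}
    col_support = {s: h / denom for s, h in col_hits.items()}
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_support": row_support,
        "col_support": col_support,
        "significant_rows": {s for s, v in row_support.items() if v >= support_threshold},
        "significant_cols": {s for s, v in col_support.items() if v >= support_threshold},
    }
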