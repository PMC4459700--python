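"""Canonical correlation, ridge-regularized CCA and two-block PLS.

The statistical core applied within each functional group and to the
undivided data. Classical CCA solves the canonical eigenproblem of
S_xx^-1 S_xy S_yy^-1 S_yx (here via SVD of the whitened cross-covariance),
attaches Bartlett chi-square p-values per variate and Stewart-Love
redundancy indices. When variables outnumber samples the within-block
covariances are ridge-regularized (S_xx + lambda1*I, S_yy + lambda2*I).
PLS extracts covariance-maximizing latent variables with per-component
explained-variance percentages for both blocks.

Sign convention throughout: each X variate is oriented so that its
largest-|loading| variable loads positively; the paired Y variate is then
oriented so the score-pair correlation is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats
from sklearn.cross_decomposition import PLSCanonical, PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "CcaResult",
    "RccaResult",
    "PlsResult",
    "compute_cca",
    "bartlett_pvalues",
    "redundancy_index",
    "compute_rcca",
    "select_lambda",
    "compute_pls",
]

_RCOND = 1e-10


@dataclass
class CcaResult:
    """Canonical correlations, variates, loadings and summaries.

    ``correlations`` holds r_1 >= ... >= r_s, s = min(p, q). Loadings are
    structural correlations: the Pearson correlation of each raw variable
    with each canonical variate of its own block. Scores have unit sample
    variance.
    """

    correlations: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    p_values: np.ndarray
    redundancy_y_given_x: float
    redundancy_x_given_y: float
    n: int
    p: int
    q: int


@dataclass
class RccaResult:
    """Like :class:`CcaResult` but ridge-regularized; no significance test
    is available (the regularized statistic has no Bartlett null)."""

    correlations: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    lambda1: float
    lambda2: float
    n: int
    p: int
    q: int


@dataclass
class PlsResult:
    """Two-block PLS latent variables with explained-variance summaries."""

    n_components: int
    mode: str
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_weights: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    explained_variance_x: np.ndarray  # percent per component
    explained_variance_y: np.ndarray


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def _inv_sqrt(S: np.ndarray, what: str) -> np.ndarray:
    w, V = scipy.linalg.eigh(S)
    tol = _RCOND * max(w.max(), 0.0)
    if w.min() <= tol:
        raise np.linalg.LinAlgError(
            f"singular within-block covariance ({what}); remove collinear "
            "variables with the correlation prefilter or use regularized CCA"
        )
    return (V * (w ** -0.5)) @ V.T


def _structural_loadings(raw: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of every raw column with every score column."""
    rc = _center(raw)
    sc = _center(scores)
    rn = np.linalg.norm(rc, axis=0)
    sn = np.linalg.norm(sc, axis=0)
    rn[rn == 0.0] = np.inf  # constant variable: loading 0 by convention
    sn = np.where(sn == 0.0, np.inf, sn)
    return (rc / rn).T @ (sc / sn)


def _canonical_core(
    X: np.ndarray, Y: np.ndarray, lambda1: float, lambda2: float
):
    """Shared CCA/rCCA solver. Returns weights, scores, loadings and the
    realized score-pair Pearson correlations after sign orientation."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    n, p = X.shape
    q = Y.shape[1]
    s = min(p, q)
    Xc, Yc = _center(X), _center(Y)
    Sxx = (Xc.T @ Xc) / (n - 1) + lambda1 * np.eye(p)
    Syy = (Yc.T @ Yc) / (n - 1) + lambda2 * np.eye(q)
    Sxy = (Xc.T @ Yc) / (n - 1)
    Wx = _inv_sqrt(Sxx, "X block")
    Wy = _inv_sqrt(Syy, "Y block")
    U, sv, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    A = Wx @ U[:, :s]  # x weight vectors (unit variance scores when lambda=0)
    B = Wy @ Vt.T[:, :s]
    x_scores = Xc @ A
    y_scores = Yc @ B
    x_load = _structural_loadings(X, x_scores)
    y_load = _structural_loadings(Y, y_scores)
    # orient: X variate by largest-|loading| positive, Y variate so that the
    # realized score correlation is non-negative
    for k in range(s):
        jx = int(np.argmax(np.abs(x_load[:, k])))
        if x_load[jx, k] < 0:
            A[:, k] *= -1
            x_scores[:, k] *= -1
            x_load[:, k] *= -1
        num = float(x_scores[:, k] @ y_scores[:, k])
        if num < 0:
            B[:, k] *= -1
            y_scores[:, k] *= -1
            y_load[:, k] *= -1
    # realized correlations of the oriented score pairs
    corr = np.empty(s)
    for k in range(s):
        xs, ys = x_scores[:, k], y_scores[:, k]
        denom = np.linalg.norm(xs - xs.mean()) * np.linalg.norm(ys - ys.mean())
        corr[k] = float((xs - xs.mean()) @ (ys - ys.mean()) / denom) if denom else 0.0
    corr = np.clip(corr, 0.0, 1.0)
    return corr, A, B, x_scores, y_scores, x_load, y_load, n, p, q, s


def compute_cca(X: np.ndarray, Y: np.ndarray) -> CcaResult:
    """Classical canonical correlation analysis of two sample-paired blocks.

    Columns are centered internally; the within-block covariances must be
    nonsingular (n > p + q is recommended). Returns correlations, unit-
    variance variates, structural loadings, Bartlett p-values per variate
    and aggregate Stewart-Love redundancies in both directions.
    """
    (corr, A, B, xs, ys, xl, yl, n, p, q, s) = _canonical_core(X, Y, 0.0, 0.0)
    res = CcaResult(
        correlations=corr,
        x_loadings=xl,
        y_loadings=yl,
        x_scores=xs,
        y_scores=ys,
        x_weights=A,
        y_weights=B,
        p_values=bartlett_pvalues(corr, n, p, q),
        redundancy_y_given_x=0.0,
        redundancy_x_given_y=0.0,
        n=n,
        p=p,
        q=q,
    )
    res.redundancy_y_given_x = redundancy_index(res, "y_given_x")
    res.redundancy_x_given_y = redundancy_index(res, "x_given_y")
    return res


def bartlett_pvalues(correlations: np.ndarray, n: int, p: int, q: int) -> np.ndarray:
    """Bartlett's sequential chi-square test for canonical correlations.

    For variate k (1-based), Wilks Lambda_k = prod_{i>=k} (1 - r_i^2),
    chi2_k = -[n - 1 - (p + q + 1)/2] * ln Lambda_k with
    (p - k + 1)(q - k + 1) degrees of freedom; the p-value is the upper
    chi-square tail. A perfect correlation collapses Lambda to 0 and yields
    p = 0 with a warning.
    """
    r = np.asarray(correlations, dtype=float)
    s = len(r)
    if np.any(r >= 1.0):
        warnings.warn(
            "canonical correlation equal to 1: Wilks Lambda is 0, p-value 0",
            stacklevel=2,
        )
    pvals = np.empty(s)
    factor = n - 1 - (p + q + 1) / 2.0
    for k in range(s):
        lam = float(np.prod(1.0 - r[k:] ** 2))
        if lam <= 0.0:
            pvals[k] = 0.0
            continue
        chi2 = -factor * np.log(lam)
        df = (p - k) * (q - k)
        pvals[k] = float(stats.chi2.sf(chi2, df))
    return pvals


def redundancy_index(
    result: "CcaResult | RccaResult",
    direction: str = "y_given_x",
    k_variates: int | None = None,
) -> float:
    """Stewart-Love redundancy: the fraction of one block's variance
    explained by the other block through the canonical variates.

    Rd(Y|X) = sum_k r_k^2 * mean_j loading_{jk}^2 over the chosen variates,
    with the Y structural loadings (mirror for X|Y). The aggregate default
    sums over all variates.
    """
    if direction == "y_given_x":
        load = result.y_loadings
    elif direction == "x_given_y":
        load = result.x_loadings
    else:
        raise ValueError(f"unknown direction {direction!r}")
    r2 = np.asarray(result.correlations) ** 2
    k = len(r2) if k_variates is None else int(k_variates)
    per_variate = r2[:k] * np.mean(load[:, :k] ** 2, axis=0)
    return float(per_variate.sum())


def compute_rcca(
    X: np.ndarray, Y: np.ndarray, lambda1: float, lambda2: float
) -> RccaResult:
    """Ridge-regularized CCA, usable when variables outnumber samples.

    The canonical eigenproblem is solved with S_xx + lambda1*I and
    S_yy + lambda2*I in place of the within-block covariances. Reported
    correlations are the plain Pearson correlations of the resulting score
    pairs (oriented non-negative). At lambda1 = lambda2 = 0 this reduces
    exactly to :func:`compute_cca` on nonsingular data.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("ridge penalties must be >= 0")
    (corr, A, B, xs, ys, xl, yl, n, p, q, s) = _canonical_core(
        X, Y, float(lambda1), float(lambda2)
    )
    # under regularization the realized score-pair correlations need not
    # follow the singular-value order exactly; variates are reported in
    # correlation order
    order = np.argsort(-corr, kind="stable")
    corr = corr[order]
    A, B = A[:, order], B[:, order]
    xs, ys = xs[:, order], ys[:, order]
    xl, yl = xl[:, order], yl[:, order]
    return RccaResult(
        correlations=corr,
        x_loadings=xl,
        y_loadings=yl,
        x_scores=xs,
        y_scores=ys,
        x_weights=A,
        y_weights=B,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        n=n,
        p=p,
        q=q,
    )


def select_lambda(
    X: np.ndarray,
    Y: np.ndarray,
    grid1,
    grid2,
    n_folds: int = 5,
    seed: int = 0,
):
    """Pick ridge penalties by cross-validated first-pair correlation.

    For every (lambda1, lambda2) grid cell, rCCA weights are fitted on the
    training folds and the held-out rows are projected; the criterion is the
    mean absolute out-of-fold Pearson correlation of the first score pair.
    Deterministic given ``seed``; ties resolve to the earliest grid cell.

    Returns ``(lambda1, lambda2, cv_table)`` with the table holding one row
    per grid cell.
    """
    grid1 = [float(g) for g in grid1]
    grid2 = [float(g) for g in grid2]
    if not grid1 or not grid2:
        raise ValueError("lambda grids must be nonempty")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, n]")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    for train, test in folds:
        if len(test) < 3 or len(train) < 3:
            raise ValueError("each fold needs at least 3 samples")
    rows = []
    best = None
    for l1 in grid1:
        for l2 in grid2:
            scores = []
            for train, test in folds:
                fit = compute_rcca(X[train], Y[train], l1, l2)
                xt = X[test] - X[train].mean(axis=0)
                yt = Y[test] - Y[train].mean(axis=0)
                u = xt @ fit.x_weights[:, 0]
                v = yt @ fit.y_weights[:, 0]
                su, sv_ = u.std(), v.std()
                if su == 0.0 or sv_ == 0.0:
                    scores.append(0.0)
                else:
                    scores.append(abs(float(np.corrcoef(u, v)[0, 1])))
            mean_cv = float(np.mean(scores))
            rows.append({"lambda1": l1, "lambda2": l2, "mean_cv_cor": mean_cv})
            if best is None or mean_cv > best[0] + 1e-12:
                best = (mean_cv, l1, l2)
    import pandas as pd

    return best[1], best[2], pd.DataFrame(rows)


def compute_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 2,
    mode: str = "canonical",
) -> PlsResult:
    """Two-block partial least squares with explained-variance summaries.

    Columns are centered and unit-scaled internally. Per component the
    weight vectors are the dominant singular pair of the current
    cross-covariance; scores are formed and the blocks deflated (regression:
    both on the X scores; canonical: each block on its own scores).
    Explained variance per block and component is the squared Frobenius norm
    of the rank-1 reconstruction as a percentage of the centered, scaled
    block's squared norm. ``n_components`` beyond the feasible rank is
    truncated with a warning.
    """
    if mode not in ("regression", "canonical"):
        raise ValueError(f"unknown PLS mode {mode!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    X0 = _scale(_center(X))
    Y0 = _scale(_center(Y))
    rank_x = np.linalg.matrix_rank(X0)
    cap = min(n - 1, p, rank_x)
    if mode == "canonical":
        cap = min(cap, q, np.linalg.matrix_rank(Y0))
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds feasible rank {cap}; truncated",
            stacklevel=2,
        )
        n_components = cap
    if n_components < 1:
        raise ValueError("need at least one extractable component")
    if mode == "regression":
        est = PLSRegression(
            n_components=n_components, scale=True, tol=1e-14, max_iter=5000
        )
    else:
        # per-component SVD of the deflated cross-covariance: exact weights
        est = PLSCanonical(n_components=n_components, scale=True, algorithm="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter near full rank
        est.fit(X, Y)
    xw = est.x_weights_.copy()
    yw = est.y_weights_.copy()
    xl = est.x_loadings_.copy()
    yl = est.y_loadings_.copy()
    # transform reproduces the fitted deflation scores on the training data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xs, ys = (M.copy() for M in est.transform(X, Y))
    for k in range(n_components):
        j = int(np.argmax(np.abs(xl[:, k])))
        if xl[j, k] < 0:  # flip both blocks to preserve cross-relations
            for M in (xw, xl, xs, yw, yl, ys):
                M[:, k] *= -1
    ev_x = np.empty(n_components)
    ev_y = np.empty(n_components)
    nx2 = float(np.sum(X0**2))
    ny2 = float(np.sum(Y0**2))
    for k in range(n_components):
        ev_x[k] = 100.0 * (xs[:, k] @ xs[:, k]) * (xl[:, k] @ xl[:, k]) / nx2
        t_for_y = xs[:, k] if mode == "regression" else ys[:, k]
        ev_y[k] = 100.0 * (t_for_y @ t_for_y) * (yl[:, k] @ yl[:, k]) / ny2
    return PlsResult(
        n_components=n_components,
        mode=mode,
        x_weights=xw,
        x_loadings=xl,
        y_weights=yw,
        y_loadings=yl,
        x_scores=xs,
        y_scores=ys,
        explained_variance_x=ev_x,
        explained_variance_y=ev_y,
    )


def _scale(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return M / sd
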