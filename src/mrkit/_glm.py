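"""Internal regression primitives.

Small, fast implementations used in hot loops (bootstrap replicates,
sliding windows, per-variant scans) where per-fit overhead of a full
model framework dominates. Correctness is pinned against statsmodels
in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit


class FitError(ValueError):
    """A regression could not be fitted (degenerate or ill-posed input)."""


def ols_fit(X: np.ndarray, y: np.ndarray):
    """Ordinary least squares with full-rank check.

    Returns ``(beta, se, resid, dof)``. Raises :class:`FitError` on a
    rank-deficient design or too few observations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise FitError("too few observations for OLS")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError("collinear design matrix")
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, resid, dof


def simple_slope(x: np.ndarray, y: np.ndarray):
    """Slope, SE and two-sided p of the simple regression y ~ 1 + x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise FitError("need at least 3 observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise FitError("zero-variance predictor")
    yc = y - y.mean()
    beta = float(xc @ yc) / sxx
    sse = float(yc @ yc) - beta * beta * sxx
    sigma2 = max(sse, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        p = 0.0
    else:
        p = 2.0 * stats.t.sf(abs(beta / se), n - 2)
    return beta, se, p


def simple_slopes(y: np.ndarray, G: np.ndarray):
    """Vectorised per-column simple regressions y ~ 1 + G[:, j].

    Returns ``(beta, se, p)`` arrays of length G.shape[1]. Columns with zero
    variance get NaN everywhere (callers drop them).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    ok = sxx > 0
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    beta[ok] = (Gc[:, ok].T @ yc) / sxx[ok]
    sse = float(yc @ yc) - beta[ok] ** 2 * sxx[ok]
    sigma2 = np.maximum(sse, 0.0) / (n - 2)
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    return beta, se, p


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Newton–Raphson logistic regression.

    Returns ``(beta, se, cov)``. Raises :class:`FitError` when the outcome
    is constant, the information matrix is singular, the iteration fails to
    converge, or coefficients diverge (separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    ncase = float(y.sum())
    if ncase == 0:
        raise FitError("no cases in outcome")
    if ncase == n:
        raise FitError("no controls in outcome")
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    H = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        if not np.all(np.isfinite(delta)):
            raise FitError("divergent logistic fit")
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    else:
        raise FitError("logistic regression did not converge")
    if np.max(np.abs(beta)) > 30.0:
        raise FitError("separation suspected (diverging coefficients)")
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return beta, se, cov


def logistic_slopes(y: np.ndarray, G: np.ndarray):
    """Per-column univariable logistic regressions y ~ 1 + G[:, j].

    Returns ``(beta, se, p)`` for the genotype coefficient; NaN for columns
    where the fit fails.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    start = None
    for j in range(m):
        Xj = np.column_stack([np.ones_like(y), G[:, j]])
        try:
            b, s, _ = logistic_fit(Xj, y, start=start)
        except FitError:
            continue
        beta[j], se[j] = b[1], s[1]
        start = np.array([b[0], 0.0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, p
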