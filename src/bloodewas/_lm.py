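"""Compact linear / logistic model fitting used throughout the package.

Per-CpG scans and the permutation loop of the causal inference test need on
the order of 10^5 small regressions; both fitters here are plain
numpy/scipy with Wald inference and are cross-checked against statsmodels
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LMFit", "ols", "logit", "drop_collinear"]

# IRLS divergence guard: |linear predictor| beyond this means fitted
# probabilities are numerically 0/1 (separation).
_ETA_MAX = 30.0


@dataclass
class LMFit:
    """Result of a least-squares or logistic fit.

    Attributes
    ----------
    params, bse, stat, pvalues : arrays aligned to the design columns.
        ``stat`` is a t statistic for OLS and a Wald z for logistic.
    converged : False when IRLS hit the iteration cap.
    separated : True when the logistic likelihood is unbounded
        (perfectly separated data); estimates are then meaningless and
        p-values are NaN.
    df_resid : residual degrees of freedom (OLS only; NaN for logistic).
    rsquared : coefficient of determination (OLS only).
    dropped : indices of design columns removed as collinear.
    """

    params: np.ndarray
    bse: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    converged: bool = True
    separated: bool = False
    df_resid: float = np.nan
    rsquared: float = np.nan
    dropped: list = field(default_factory=list)


def drop_collinear(X: np.ndarray, tol: float = 1e-8):
    """Return (kept column indices, dropped column indices) via pivoted QR."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    kept: list[int] = []
    dropped: list[int] = []
    # Greedy left-to-right: keep a column only if it adds numerical rank.
    for j in range(X.shape[1]):
        sub = X[:, kept + [j]]
        s = np.linalg.svd(sub, compute_uv=False)
        if s[-1] > tol * max(s[0], 1.0):
            kept.append(j)
        else:
            dropped.append(j)
    return kept, dropped


def _expand(fit_params, fit_bse, fit_stat, fit_p, kept, p_total):
    params = np.full(p_total, np.nan)
    bse = np.full(p_total, np.nan)
    stat = np.full(p_total, np.nan)
    pv = np.full(p_total, np.nan)
    params[kept] = fit_params
    bse[kept] = fit_bse
    stat[kept] = fit_stat
    pv[kept] = fit_p
    return params, bse, stat, pv


def ols(X: np.ndarray, y: np.ndarray, check_rank: bool = True) -> LMFit:
    """Ordinary least squares with t-based Wald inference.

    Collinear columns are dropped (recorded in ``dropped``) and their
    entries reported as NaN, mirroring how a careful analyst would treat a
    rank-deficient design rather than silently pinv-ing through it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if check_rank:
        kept, dropped = drop_collinear(X)
    else:
        kept, dropped = list(range(p)), []
    Xk = X[:, kept]
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    df = n - len(kept)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    bse = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / bse
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    params, bse, tstat, pv = _expand(beta, bse, tstat, pv, kept, p)
    return LMFit(params, bse, tstat, pv, df_resid=df, rsquared=r2, dropped=dropped)


def logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    check_rank: bool = True,
) -> LMFit:
    """Logistic regression by IRLS (Newton-Raphson) with Wald z inference.

    Detects perfect separation (all fitted probabilities pinned to the
    observed class) and reports it via ``separated`` with NaN p-values
    instead of a spuriously tiny one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    n, p = X.shape
    if check_rank:
        kept, dropped = drop_collinear(X)
    else:
        kept, dropped = list(range(p)), []
    Xk = X[:, kept]
    beta = np.zeros(len(kept))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xk @ beta, -_ETA_MAX, _ETA_MAX)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # Fisher scoring step with a tiny ridge for numerical safety.
        XtW = Xk.T * w
        H = XtW @ Xk + 1e-12 * np.eye(len(kept))
        g = Xk.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xk @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_MAX, _ETA_MAX)))
    separated = bool(np.all(np.abs(y - mu) < 1e-6)) or bool(
        np.max(np.abs(eta)) > 2 * _ETA_MAX
    )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (Xk.T * w) @ Xk
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        bse = np.full(len(kept), np.nan)
        separated = True
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / bse
    pv = 2.0 * stats.norm.sf(np.abs(z))
    if separated:
        pv = np.full(len(kept), np.nan)
    params, bse, z, pv = _expand(beta, bse, z, pv, kept, p)
    return LMFit(params, bse, z, pv, converged=converged, separated=separated, dropped=dropped)
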