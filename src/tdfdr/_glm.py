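"""Batched GLM fitting across many outcome features sharing one design matrix.

Feature-wise association scans refit the same small design against thousands
of outcome columns, and the bootstrap null calibration multiplies that by
B+1.  Per-feature fits through a generic GLM interface are the bottleneck, so
the Wald machinery is vectorized here: ordinary least squares in closed form
for the gaussian family, and an IRLS Newton iteration carried simultaneously
over all features for binomial/poisson.

Features whose fit fails (divergence, separation, zero residual variance,
singular information) are reported through ``ok`` masks; callers assign the
sentinel statistic 0 so such features are never rejected.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = ["batched_wald"]

_MAX_ITER = 40
_TOL = 1e-9
_ETA_CAP = 30.0  # |linear predictor| beyond this signals separation/divergence


def _ols_wald(D: np.ndarray, Y: np.ndarray, block: slice):
    """Gaussian-family Wald statistics for the coefficient block, all features at once."""
    n, p = D.shape
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (D.T @ Y)  # (p, m)
    resid = Y - D @ beta
    dof = n - p
    rss = np.einsum("nm,nm->m", resid, resid)
    sigma2 = rss / dof
    ok = sigma2 > 1e-12 * np.maximum(1.0, np.einsum("nm,nm->m", Y, Y) / n)
    sigma2 = np.where(ok, sigma2, np.nan)
    idx = np.arange(p)[block]
    if idx.size == 1:
        k = idx[0]
        se = np.sqrt(sigma2 * Ginv[k, k])
        stat = np.abs(beta[k] / se)
    else:
        Vinv = np.linalg.inv(Ginv[np.ix_(idx, idx)])  # (k, k)
        b = beta[idx]  # (k, m)
        chi2 = np.einsum("km,kl,lm->m", b, Vinv, b) / sigma2
        stat = np.sqrt(np.clip(chi2, 0.0, None))
    ok = ok & np.isfinite(stat)
    return np.where(ok, stat, 0.0), ok


def _irls_wald(D: np.ndarray, Y: np.ndarray, family: str, block: slice):
    """Binomial/poisson Wald statistics via Newton-Raphson batched over features."""
    n, p = D.shape
    m = Y.shape[1]
    beta = np.zeros((m, p))
    if family == "binomial":
        ybar = np.clip(Y.mean(axis=0), 1e-3, 1 - 1e-3)
        beta[:, 0] = np.log(ybar / (1 - ybar))
    else:
        beta[:, 0] = np.log(np.clip(Y.mean(axis=0), 1e-3, None))
    alive = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    XtWX = np.zeros((m, p, p))
    eye = np.eye(p)

    for _ in range(_MAX_ITER):
        eta = D @ beta.T  # (n, m)
        if family == "binomial":
            mu = expit(eta)
            W = mu * (1 - mu)
        else:
            mu = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
            W = mu
        W = np.clip(W, 1e-10, None)
        score = np.einsum("np,nm->mp", D, Y - mu)
        XtWX = np.einsum("np,nm,nq->mpq", D, W, D)
        # ridge-free Newton step; singular information marks the feature dead
        try:
            step = np.linalg.solve(XtWX + 1e-12 * eye, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.full((m, p), np.nan)
        beta_new = beta + step
        delta = np.max(np.abs(step), axis=1)
        diverged = (
            ~np.isfinite(delta)
            | (np.max(np.abs(D @ beta_new.T), axis=0) > _ETA_CAP)
        )
        alive &= ~diverged
        newly = alive & ~converged & (delta < _TOL)
        converged |= newly
        upd = alive & ~converged
        beta[upd] = beta_new[upd]
        if not upd.any():
            break

    ok = alive & converged
    idx = np.arange(p)[block]
    stat = np.zeros(m)
    if ok.any():
        cov = np.linalg.inv(XtWX[ok])
        if idx.size == 1:
            k = idx[0]
            se = np.sqrt(np.clip(cov[:, k, k], 1e-300, None))
            stat[ok] = np.abs(beta[ok, k] / se)
        else:
            Vb = cov[:, idx][:, :, idx]
            b = beta[ok][:, idx]
            chi2 = np.einsum("mk,mkl,ml->m", b, np.linalg.inv(Vb), b)
            stat[ok] = np.sqrt(np.clip(chi2, 0.0, None))
    bad = ~np.isfinite(stat)
    stat[bad] = 0.0
    ok &= ~bad
    return stat, ok


def batched_wald(design: np.ndarray, Y: np.ndarray, family: str, block: slice):
    """Wald statistics |z| (or sqrt of the block Wald chi-square) for one
    coefficient block, computed for every feature column of ``Y``.

    Parameters
    ----------
    design : (n, p) design matrix including the intercept column.
    Y : (n, m) outcome matrix.
    family : "gaussian", "binomial" or "poisson".
    block : slice selecting the tested coefficient(s) within ``design``.

    Returns
    -------
    stat : (m,) non-negative statistics, 0 for failed fits.
    ok : (m,) boolean mask of successful fits.
    """
    design = np.asarray(design, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient; drop collinear columns")
    if family == "gaussian":
        stat, ok = _ols_wald(design, Y, block)
    elif family in ("binomial", "poisson"):
        stat, ok = _irls_wald(design, Y, family, block)
    else:
        raise ValueError(f"unknown family {family!r}")
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "%d of %d features failed to fit (family=%s); assigned statistic 0",
            n_bad, Y.shape[1], family,
        )
    return stat, ok
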