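"""Paired marginal/conditional independence statistics (T^M, T^C).

Three interchangeable engines compute, for every feature Y_j, a marginal
statistic T^M testing Y_j independent of X (ignoring Z) and a conditional
statistic T^C testing Y_j independent of X given Z.  All statistics are
oriented so that large positive values are evidence against the null:

* ``glm``  — absolute Wald z/t statistics from GLM fits; the conditional
  statistic comes from the confounder-adjusted (full) model, the marginal one
  from the reduced model omitting Z.  Categorical X emits the square root of
  the block Wald chi-square.
* ``rv``   — the RV matrix-correlation coefficient (squared Pearson
  correlation in the univariate case); the conditional version is computed on
  residuals from natural-cubic-spline regressions of X and Y_j on Z.
* ``hsic`` — biased empirical Hilbert-Schmidt independence criterion with
  Gaussian kernels and median-heuristic bandwidths; the conditional version
  residualizes the X and Y kernels against a Tikhonov-regularized Z-kernel
  operator.
"""

from __future__ import annotations

import logging

import numpy as np

from ._glm import batched_wald
from .data import (
    ConfounderMatrix,
    CovariateVector,
    FeatureMatrix,
    StatPair,
    check_alignment,
)
from .splines import natural_cubic_basis

logger = logging.getLogger(__name__)

__all__ = ["glm_stat_pair", "rv_stat_pair", "hsic_stat_pair", "compute_stat_pair"]


# ---------------------------------------------------------------------------
# model-based engine
# ---------------------------------------------------------------------------

def _name_collinear(design: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(design)
    bad = []
    for k in range(design.shape[1]):
        rest = np.delete(design, k, axis=1)
        if np.linalg.matrix_rank(rest) == rank:
            bad.append(names[k])
    return bad


def glm_stat_pair(
    Y: FeatureMatrix, X: CovariateVector, Z: ConfounderMatrix
) -> StatPair:
    """Wald statistic pairs from full (with Z) and reduced (without Z) GLM fits.

    The GLM family/link follows ``Y.outcome_family``: gaussian/identity,
    binomial/logit, poisson/log.  Features whose fit fails (separation,
    divergence, zero residual variance) receive the sentinel statistic 0 and
    a logged warning rather than aborting the scan.
    """
    check_alignment(Y, X, Z)
    n = Y.n
    Xd = X.design()
    Zd = Z.design()
    ones = np.ones((n, 1))
    block = slice(1, 1 + Xd.shape[1])

    full = np.column_stack([ones, Xd, Zd])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        names = (
            ["intercept"]
            + [f"X[{k}]" for k in range(Xd.shape[1])]
            + [f"Z[{k}]" for k in range(Zd.shape[1])]
        )
        raise ValueError(
            f"rank-deficient design; collinear columns: {_name_collinear(full, names)}"
        )
    t_cond, _ = batched_wald(full, Y.values, Y.outcome_family, block)
    reduced = np.column_stack([ones, Xd])
    t_marg, _ = batched_wald(reduced, Y.values, Y.outcome_family, block)
    return StatPair(t_marg, t_cond, engine="glm")


# ---------------------------------------------------------------------------
# RV-coefficient engine
# ---------------------------------------------------------------------------

def _rv_univariate_many(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """RV(a, B[:, j]) for a single centered column ``a`` against every
    centered column of ``B``; equals the squared Pearson correlation."""
    na = a @ a
    nb = np.einsum("nm,nm->m", B, B)
    cross = a @ B
    denom = na * nb
    out = np.zeros(B.shape[1])
    good = denom > 0
    out[good] = cross[good] ** 2 / denom[good]
    return np.clip(out, 0.0, 1.0)


def _rv_general(A: np.ndarray, B: np.ndarray) -> float:
    """RV coefficient of two centered blocks: ||A'B||_F^2 / (||A'A||_F ||B'B||_F)."""
    saa = np.linalg.norm(A.T @ A)
    sbb = np.linalg.norm(B.T @ B)
    if saa == 0 or sbb == 0:
        return 0.0
    return float(np.linalg.norm(A.T @ B) ** 2 / (saa * sbb))


def confounder_spline_design(Z: ConfounderMatrix, spline_df: int) -> np.ndarray:
    """Residualization design for Z: natural cubic spline basis per continuous
    column, indicator contrasts per categorical column, plus an intercept."""
    cols = [np.ones((Z.n, 1))]
    for j, kind in enumerate(Z.kinds):
        col = Z.values[:, j]
        if kind == "categorical":
            levels, codes = np.unique(col, return_inverse=True)
            for lev in range(1, len(levels)):
                cols.append((codes == lev).astype(float)[:, None])
        else:
            cols.append(natural_cubic_basis(np.asarray(col, dtype=float), spline_df))
    D = np.column_stack(cols)
    # prune degenerate columns (e.g. constant Z duplicating the intercept) so
    # the QR projection spans exactly the intended space
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return D[:, keep]


def _residualize(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(design)
    return M - Q @ (Q.T @ M)


def rv_stat_pair(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    spline_df: int = 4,
) -> StatPair:
    """RV-coefficient statistic pairs.

    T^M = RV(X, Y_j) on column-centered data; T^C = RV on the residuals of X
    and Y_j from natural-cubic-spline regressions on Z with ``spline_df``
    basis columns per continuous confounder (``spline_df=1`` reduces to
    linear adjustment).  Zero-variance inputs yield statistic 0.
    """
    check_alignment(Y, X, Z)
    if X.kind == "categorical":
        raise ValueError("rv engine requires a numeric covariate")
    n = Y.n
    if spline_df >= n:
        raise ValueError(f"spline_df={spline_df} must be < n={n}")
    Xd = X.design()
    Yv = Y.values
    Xc = Xd - Xd.mean(axis=0)
    Yc = Yv - Yv.mean(axis=0)
    if (Xc.std(axis=0) == 0).any():
        logger.warning("zero-variance covariate column; marginal RV set to 0")
    design = confounder_spline_design(Z, spline_df)
    Xr = _residualize(Xc, design)
    Yr = _residualize(Yc, design)
    if Xd.shape[1] == 1:
        t_marg = _rv_univariate_many(Xc[:, 0], Yc)
        t_cond = _rv_univariate_many(Xr[:, 0], Yr)
    else:
        t_marg = np.array([_rv_general(Xc, Yc[:, [j]]) for j in range(Y.m)])
        t_cond = np.array([_rv_general(Xr, Yr[:, [j]]) for j in range(Y.m)])
    return StatPair(t_marg, t_cond, engine="rv")


# ---------------------------------------------------------------------------
# HSIC engine
# ---------------------------------------------------------------------------

def _standardize(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return M / sd


def _gaussian_kernel(M: np.ndarray) -> np.ndarray | None:
    """Gaussian kernel with median-heuristic bandwidth on the standardized
    columns of ``M``; None when all pairwise distances are zero."""
    M = _standardize(np.atleast_2d(np.asarray(M, dtype=float).T).T)
    sq = np.sum(M**2, axis=1)
    D2 = np.clip(sq[:, None] + sq[None, :] - 2 * M @ M.T, 0.0, None)
    iu = np.triu_indices_from(D2, k=1)
    dists = np.sqrt(D2[iu])
    dists = dists[dists > 0]
    if dists.size == 0:
        return None
    sigma = np.median(dists)
    return np.exp(-D2 / (2 * sigma**2))


def hsic_stat_pair(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    epsilon: float = 0.001,
) -> StatPair:
    """HSIC statistic pairs with Gaussian kernels and median-heuristic bandwidths.

    T^M_j = tr(H K_X H L_j) / n^2 (biased empirical HSIC).  T^C_j residualizes
    the centered X and Y_j kernels against Z through the regularized operator
    R = G_Z (G_Z + n*eps*I)^{-1}: with P = I - R,
    T^C_j = tr(P G_X P * P G_{Y_j} P) / n^2, where G denotes a centered kernel.
    """
    check_alignment(Y, X, Z)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n = Y.n
    if n < 5:
        raise ValueError("hsic engine requires n >= 5")
    H = np.eye(n) - np.ones((n, n)) / n

    Kx = _gaussian_kernel(X.design())
    Kz = _gaussian_kernel(Z.design())
    if Kx is None:
        logger.warning("constant covariate: all HSIC statistics set to 0")
        return StatPair(np.zeros(Y.m), np.zeros(Y.m), engine="hsic")
    Gx = H @ Kx @ H
    Gz = H @ (Kz if Kz is not None else np.zeros((n, n))) @ H
    R = Gz @ np.linalg.inv(Gz + n * epsilon * np.eye(n))
    P = np.eye(n) - R
    # tr(P Gx P . P Gy P) = tr((P^2 Gx P^2) H Ly H) = sum((H P^2 Gx P^2 H) * Ly)
    P2 = P @ P
    Mcond = H @ (P2 @ Gx @ P2) @ H
    Mmarg = H @ Gx @ H  # tr(Gx H Ly H) = sum((H Gx H) * Ly)

    t_marg = np.zeros(Y.m)
    t_cond = np.zeros(Y.m)
    for j in range(Y.m):
        Ly = _gaussian_kernel(Y.values[:, j])
        if Ly is None:
            logger.warning("feature %d constant: HSIC set to 0", j)
            continue
        t_marg[j] = np.sum(Mmarg * Ly) / n**2
        t_cond[j] = np.sum(Mcond * Ly) / n**2
    return StatPair(np.clip(t_marg, 0, None), np.clip(t_cond, 0, None), engine="hsic")


_ENGINES = {"glm": glm_stat_pair, "rv": rv_stat_pair, "hsic": hsic_stat_pair}


def compute_stat_pair(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    engine: str = "rv",
    **engine_kwargs,
) -> StatPair:
    """Dispatch to one of the three engines by name."""
    try:
        fn = _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(_ENGINES)}")
    return fn(Y, X, Z, **engine_kwargs)
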