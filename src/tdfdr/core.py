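"""Cutoff search and error-rate control on the (T^M, T^C) plane.

Given observed statistic pairs and their resampled null counterparts, this
module estimates the false discovery proportion over a 2D grid of candidate
cutoffs, sharpens it with a Storey-type null-proportion estimate, and selects
the cutoff pair that maximizes rejections subject to the FDP estimate staying
at or below the target level q.  The 1D special case (no marginal screening)
and a family-wise error rate variant share the same machinery.

The per-feature null exceedance probability is estimated by

    Fbar_{j,B}(t1, t2) = (1/(B+1)) * sum_{b=0}^{B} 1{T^M_{j,b} >= t1, T^C_{j,b} >= t2}

with b = 0 the observed pair, and the FDP estimate at (t1, t2) is

    pi0_hat * sum_j Fbar_{j,B}(t1, t2) / max(1, #{j : T^M_j >= t1, T^C_j >= t2}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conditional_sampler import (
    ConditionalSampler,
    NullStatArray,
    compute_null_stats,
    fit_conditional,
)
from .data import ConfounderMatrix, CovariateVector, FeatureMatrix, StatPair
from .stats_engines import compute_stat_pair

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffGrid",
    "FdpSurface",
    "CutoffSearchResult",
    "build_grid",
    "fbar",
    "estimate_pi0",
    "fdp_surface",
    "select_cutoffs",
    "run_2dfdr",
    "run_1dfdr",
    "run_2dfwer",
    "bh_reference",
]


@dataclass
class CutoffGrid:
    """Candidate cutoffs: s1 over the marginal axis, s2 over the conditional axis.

    s1 always contains the minimum observed T^M as a sentinel, so "no marginal
    screening" (the 1D procedure) is a member of the search space.
    """

    s1: np.ndarray
    s2: np.ndarray
    nu: int

    def __post_init__(self) -> None:
        self.s1 = np.unique(np.asarray(self.s1, dtype=float))
        self.s2 = np.unique(np.asarray(self.s2, dtype=float))


def build_grid(stats: StatPair, nu: int = 100, one_dimensional: bool = False) -> CutoffGrid:
    """nu evenly spaced order statistics per axis, plus the marginal sentinel.

    ``one_dimensional=True`` collapses s1 to the sentinel alone, which turns
    the search into the classical single-statistic procedure.
    """
    if nu < 1:
        raise ValueError("nu must be >= 1")
    tM, tC = stats.t_marginal, stats.t_conditional
    m = stats.m
    ranks = np.unique(np.ceil(np.arange(1, nu + 1) * m / nu).astype(int) - 1)
    ranks = ranks[(ranks >= 0) & (ranks < m)]
    sC = np.sort(tC)[ranks]
    # sentinel at the statistic floor: statistics are non-negative, so t1 = 0
    # rejects no feature on the marginal axis and reproduces the 1D procedure
    # (auxiliary cutoff forced to zero) exactly, resampled pairs included
    if one_dimensional:
        sM = np.array([0.0])
    else:
        sM = np.concatenate([[0.0], np.sort(tM)[ranks]])
    return CutoffGrid(sM, sC, nu)


@dataclass
class FdpSurface:
    """FDP estimates and rejection counts over the cutoff grid."""

    fdp: np.ndarray          # |s1| x |s2|
    rejections: np.ndarray   # |s1| x |s2| integer
    pi0: float = 1.0
    lam: float | None = None


@dataclass
class CutoffSearchResult:
    """Selected cutoff pair, the rejection set, and the FDP estimate there."""

    t1_star: float
    t2_star: float
    rejected: np.ndarray
    fdp_at_optimum: float
    n_rejections: int
    mode: str = "fdr_2d"
    pi0: float = 1.0
    stats: StatPair | None = None
    nulls: NullStatArray | None = None
    grid: CutoffGrid | None = None
    surface: FdpSurface | None = None
    sampler: ConditionalSampler | None = None
    dropped_features: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def fbar(nulls: NullStatArray, j: int, t1: float, t2: float) -> float:
    """Monte-Carlo estimate of the null probability that feature j's pair
    lands in the rejection region [t1, inf) x [t2, inf)."""
    hit = (nulls.marginal[:, j] >= t1) & (nulls.conditional[:, j] >= t2)
    return float(hit.sum()) / (nulls.B + 1)


def estimate_pi0(nulls: NullStatArray, lam: float) -> float:
    """Storey-type null-proportion estimate anchored at lambda:
    min(1, #{j: T^C_j <= lam} / sum_j F_{j,B}(lam))."""
    num = float((nulls.conditional[0] <= lam).sum())
    den = float((nulls.conditional <= lam).sum()) / (nulls.B + 1)
    if den == 0:
        logger.warning("pi0 denominator is 0 at lambda=%g; returning 1", lam)
        return 1.0
    return min(1.0, num / den)


def default_lambda(nulls: NullStatArray) -> float:
    """Median of the pooled resampled conditional statistics (rows 1..B)."""
    pool = nulls.conditional[1:] if nulls.B >= 1 else nulls.conditional[:1]
    return float(np.median(pool))


def _exceedance_counts(
    vm: np.ndarray, vc: np.ndarray, s1: np.ndarray, s2: np.ndarray
) -> np.ndarray:
    """counts[a, b] = #{points with vm >= s1[a] and vc >= s2[b]} via a 2D
    histogram followed by suffix sums (exact for >= threshold semantics)."""
    i1 = np.searchsorted(s1, vm.ravel(), side="right") - 1
    i2 = np.searchsorted(s2, vc.ravel(), side="right") - 1
    keep = (i1 >= 0) & (i2 >= 0)
    hist = np.zeros((s1.size, s2.size))
    np.add.at(hist, (i1[keep], i2[keep]), 1.0)
    return np.cumsum(np.cumsum(hist[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]


def fdp_surface(
    stats: StatPair,
    nulls: NullStatArray,
    grid: CutoffGrid,
    use_pi0: bool = True,
    lam: float | None = None,
) -> FdpSurface:
    """FDP estimate at every grid cell (vectorized, exact)."""
    if lam is None:
        lam = default_lambda(nulls)
    pi0 = estimate_pi0(nulls, lam) if use_pi0 else 1.0
    numer = _exceedance_counts(nulls.marginal, nulls.conditional, grid.s1, grid.s2)
    numer /= nulls.B + 1
    rej = _exceedance_counts(stats.t_marginal, stats.t_conditional, grid.s1, grid.s2)
    fdp = pi0 * numer / np.maximum(1.0, rej)
    return FdpSurface(fdp, rej.astype(int), pi0=pi0, lam=lam)


def select_cutoffs(
    surface: FdpSurface,
    grid: CutoffGrid,
    q: float,
    stats: StatPair | None = None,
    mode: str = "fdr_2d",
) -> CutoffSearchResult:
    """Rejection-maximizing grid point with FDP estimate <= q.

    Ties are broken deterministically: smaller FDP estimate, then larger t2,
    then larger t1.  An empty feasible set yields zero rejections with both
    cutoffs at +inf.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    feasible = surface.fdp <= q
    if not feasible.any():
        rejected = np.array([], dtype=int)
        return CutoffSearchResult(
            np.inf, np.inf, rejected, 0.0, 0, mode=mode, pi0=surface.pi0
        )
    aa, bb = np.nonzero(feasible)
    rej = surface.rejections[aa, bb]
    fdp = surface.fdp[aa, bb]
    t1 = grid.s1[aa]
    t2 = grid.s2[bb]
    order = np.lexsort((-t1, -t2, fdp, -rej))  # primary key last
    k = order[0]
    t1s, t2s = float(t1[k]), float(t2[k])
    if stats is not None:
        rejected = np.nonzero(
            (stats.t_marginal >= t1s) & (stats.t_conditional >= t2s)
        )[0]
    else:
        rejected = np.array([], dtype=int)
    return CutoffSearchResult(
        t1s, t2s, rejected, float(fdp[k]), int(rej[k]), mode=mode, pi0=surface.pi0
    )


# ---------------------------------------------------------------------------
# end-to-end procedures
# ---------------------------------------------------------------------------

def _drop_constant(Y: FeatureMatrix):
    keep = Y.values.std(axis=0) > 0
    if keep.all():
        return Y, np.arange(Y.m), np.array([], dtype=int)
    dropped = np.nonzero(~keep)[0]
    logger.warning(
        "dropping %d constant feature(s) before inference: %s",
        dropped.size, [Y.feature_ids[j] for j in dropped[:10]],
    )
    sub = FeatureMatrix(
        Y.values[:, keep],
        [Y.feature_ids[j] for j in np.nonzero(keep)[0]],
        Y.outcome_family,
    )
    return sub, np.nonzero(keep)[0], dropped


def _prepare(Y, X, Z, engine, sampler_method, B, seed, residual_bootstrap, engine_kwargs):
    Ysub, keep, dropped = _drop_constant(Y)
    sampler = fit_conditional(X, Z, sampler_method, residual_bootstrap=residual_bootstrap)
    nulls = compute_null_stats(
        Ysub, Z, sampler, engine=engine, B=B, seed=seed, X_observed=X, **engine_kwargs
    )
    return Ysub, keep, dropped, sampler, nulls


def run_2dfdr(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    engine: str = "rv",
    sampler_method: str | None = None,
    q: float = 0.05,
    B: int = 100,
    nu: int = 100,
    use_pi0: bool = True,
    lam: float | None = None,
    seed: int = 0,
    residual_bootstrap: bool = False,
    _one_dimensional: bool = False,
    **engine_kwargs,
) -> CutoffSearchResult:
    """The full two-dimensional FDR procedure.

    Pipeline: statistic pairs -> conditional sampler -> B resampled pairs ->
    cutoff grid -> FDP surface -> rejection-maximizing feasible cutoff pair.
    Deterministic given ``seed``.
    """
    if Y.m == 0:
        return CutoffSearchResult(np.inf, np.inf, np.array([], int), 0.0, 0)
    Ysub, keep, dropped, sampler, nulls = _prepare(
        Y, X, Z, engine, sampler_method, B, seed, residual_bootstrap, engine_kwargs
    )
    stats = nulls.observed
    grid = build_grid(stats, nu, one_dimensional=_one_dimensional)
    surface = fdp_surface(stats, nulls, grid, use_pi0=use_pi0, lam=lam)
    res = select_cutoffs(
        surface, grid, q, stats, mode="fdr_1d" if _one_dimensional else "fdr_2d"
    )
    res.rejected = keep[res.rejected]
    res.stats, res.nulls, res.grid, res.surface = stats, nulls, grid, surface
    res.sampler, res.dropped_features = sampler, dropped
    res.params = dict(
        engine=engine, sampler_method=sampler.method, q=q, B=B, nu=nu,
        use_pi0=use_pi0, lam=surface.lam, pi0=surface.pi0, seed=seed,
        **engine_kwargs,
    )
    return res


def run_1dfdr(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    engine: str = "rv",
    sampler_method: str | None = None,
    q: float = 0.05,
    B: int = 100,
    nu: int = 100,
    use_pi0: bool = True,
    lam: float | None = None,
    seed: int = 0,
    residual_bootstrap: bool = False,
    **engine_kwargs,
) -> CutoffSearchResult:
    """The 1D special case: the marginal cutoff is pinned at the sentinel, so
    features are called on the conditional statistic alone."""
    return run_2dfdr(
        Y, X, Z, engine=engine, sampler_method=sampler_method, q=q, B=B, nu=nu,
        use_pi0=use_pi0, lam=lam, seed=seed, residual_bootstrap=residual_bootstrap,
        _one_dimensional=True, **engine_kwargs,
    )


def run_2dfwer(
    Y: FeatureMatrix,
    X: CovariateVector,
    Z: ConfounderMatrix,
    engine: str = "rv",
    sampler_method: str | None = None,
    alpha: float = 0.05,
    B: int = 100,
    nu: int = 100,
    seed: int = 0,
    residual_bootstrap: bool = False,
    **engine_kwargs,
) -> CutoffSearchResult:
    """Family-wise error variant: the error estimate at (t1, t2) is the
    fraction of resampled replicates in which ANY feature's pair enters the
    rejection region; cutoffs maximize rejections subject to estimate <= alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if B < 1:
        raise ValueError("FWER calibration needs B >= 1")
    if Y.m == 0:
        return CutoffSearchResult(np.inf, np.inf, np.array([], int), 0.0, 0, mode="fwer_2d")
    Ysub, keep, dropped, sampler, nulls = _prepare(
        Y, X, Z, engine, sampler_method, B, seed, residual_bootstrap, engine_kwargs
    )
    stats = nulls.observed
    # grid from the POOLED rows: a grid anchored on the observed order
    # statistics would put row 0's pairs exactly on cell corners, an
    # asymmetry that leaks level under the exchangeability argument below
    pool_m = np.sort(nulls.marginal.ravel())
    pool_c = np.sort(nulls.conditional.ravel())
    ranks = np.unique(
        np.ceil(np.arange(1, nu + 1) * pool_m.size / nu).astype(int) - 1
    )
    grid = CutoffGrid(np.concatenate([[0.0], pool_m[ranks]]), pool_c[ranks], nu)
    # any-hit estimate over ALL rows (b=0 included: under the global null the
    # observed row is exchangeable with the replicates, and row symmetry is
    # what makes the calibration below exact)
    hits = []
    any_hit = np.zeros((grid.s1.size, grid.s2.size))
    for b in range(B + 1):
        cnt = _exceedance_counts(nulls.marginal[b], nulls.conditional[b], grid.s1, grid.s2)
        hits.append(cnt > 0)
        any_hit += hits[-1]
    fwer = any_hit / (B + 1)
    # calibrate the working level for the multiplicity of the cell search:
    # e_r = cheapest cell (by the any-hit estimate) at which row r's pairs
    # would produce a rejection; the search run at level alpha' rejects for
    # row r iff e_r <= alpha'.  alpha' is set to the largest value such that
    # at most an alpha-fraction of rows would reject.  Because alpha' depends
    # on the rows only through the exchangeable set {e_r}, the FWER
    # P(e_0 <= alpha') is at most alpha under the global null.
    e = np.array([
        fwer[h].min() if h.any() else np.inf for h in hits
    ])
    n_ok = np.floor(alpha * (B + 1))
    candidates = np.sort(e[np.isfinite(e)])
    alpha_work = -np.inf
    for val in candidates:
        if (e <= val).sum() <= n_ok:
            alpha_work = val
    rej = _exceedance_counts(stats.t_marginal, stats.t_conditional, grid.s1, grid.s2)
    surface = FdpSurface(fwer, rej.astype(int), pi0=1.0)
    if np.isneginf(alpha_work):
        res = CutoffSearchResult(
            np.inf, np.inf, np.array([], int), 0.0, 0, mode="fwer_2d"
        )
    else:
        res = select_cutoffs(surface, grid, alpha_work, stats, mode="fwer_2d")
    # report the calibrated FWER estimate (fraction of rows the search rejects)
    res.fdp_at_optimum = float((e <= alpha_work).sum() / (B + 1))
    res.rejected = keep[res.rejected]
    res.stats, res.nulls, res.grid, res.surface = stats, nulls, grid, surface
    res.sampler, res.dropped_features = sampler, dropped
    res.params = dict(
        engine=engine, sampler_method=sampler.method, alpha=alpha,
        alpha_work=float(alpha_work), B=B, nu=nu, seed=seed, **engine_kwargs,
    )
    return res


def bh_reference(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set (comparator)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.nonzero(rejected)[0]
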