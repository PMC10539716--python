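"""Estimation of P(X|Z) and the bootstrap replicates that calibrate the joint null.

The validity of the whole procedure rests on resampling the covariate from
(an estimate of) its conditional law given the confounders, holding Y and Z
fixed.  Under any feature's null hypothesis Y_j is independent of X given Z,
so replacing X by a replicate X~_b ~ P(X|Z) leaves the joint distribution of
the statistic pair unchanged — the resampled pairs form an empirical joint
null for (T^M_j, T^C_j).

Supported estimators: gaussian linear / gaussian spline regressions for a
continuous covariate, logistic / multinomial regressions for a binary /
categorical one, and plain permutation (valid only when X is independent
of Z).  A residual-bootstrap flag swaps normal draws for resampled empirical
residuals in the gaussian samplers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import (
    ConfounderMatrix,
    CovariateVector,
    FeatureMatrix,
    StatPair,
    check_alignment,
)
from .splines import natural_cubic_basis
from .stats_engines import compute_stat_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalSampler",
    "NullStatArray",
    "fit_conditional",
    "sample_covariates",
    "compute_null_stats",
]

_METHODS = ("gaussian_linear", "gaussian_spline", "logistic", "multinomial", "permutation")

_DEFAULT_METHOD = {
    "continuous": "gaussian_linear",
    "binary": "logistic",
    "categorical": "multinomial",
}


def _spline_or_linear_design(Z: ConfounderMatrix, spline_df: int | None) -> np.ndarray:
    cols = [np.ones((Z.n, 1))]
    for j, kind in enumerate(Z.kinds):
        col = Z.values[:, j]
        if kind == "categorical":
            levels, codes = np.unique(col, return_inverse=True)
            for lev in range(1, len(levels)):
                cols.append((codes == lev).astype(float)[:, None])
        elif spline_df is not None:
            cols.append(natural_cubic_basis(np.asarray(col, dtype=float), spline_df))
        else:
            cols.append(np.asarray(col, dtype=float)[:, None])
    D = np.column_stack(cols)
    # drop exactly-duplicated/degenerate columns (e.g. a constant Z) keeping rank
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return D[:, keep]


@dataclass
class ConditionalSampler:
    """Fitted representation of P^(X|Z), able to emit i.i.d. covariate replicates."""

    method: str
    kind: str
    n: int
    design: np.ndarray | None = None
    coef: np.ndarray | None = None          # regression coefficients / logits
    resid_sd: float | None = None           # gaussian residual scale
    residuals: np.ndarray | None = None     # for the residual bootstrap
    probs: np.ndarray | None = None         # (n, k) level probabilities
    levels: np.ndarray | None = None        # categorical level values
    observed: np.ndarray | None = None      # for permutation
    residual_bootstrap: bool = False

    @property
    def fitted_mean(self) -> np.ndarray:
        if self.method not in ("gaussian_linear", "gaussian_spline"):
            raise ValueError("fitted_mean defined only for gaussian samplers")
        return self.design @ self.coef

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One replicate covariate vector of length n, same kind as observed X."""
        if self.method == "permutation":
            return self.observed[rng.permutation(self.n)]
        if self.method in ("gaussian_linear", "gaussian_spline"):
            mu = self.fitted_mean
            if self.residual_bootstrap:
                eps = rng.choice(self.residuals, size=self.n, replace=True)
            else:
                eps = rng.normal(0.0, self.resid_sd, size=self.n)
            return mu + eps
        # logistic / multinomial: sample a level per sample from fitted probs
        u = rng.random(self.n)
        cum = np.cumsum(self.probs, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        if self.method == "logistic":
            return idx.astype(float)
        return self.levels[idx]

    def to_config(self) -> str:
        """Plain-text (JSON) dump of the fitted parameters for provenance."""
        payload = {"method": self.method, "kind": self.kind, "n": self.n}
        if self.coef is not None:
            payload["coef"] = np.asarray(self.coef).ravel().tolist()
        if self.resid_sd is not None:
            payload["resid_sd"] = float(self.resid_sd)
        if self.probs is not None:
            payload["probs"] = np.asarray(self.probs).tolist()
        if self.levels is not None:
            payload["levels"] = [str(v) for v in self.levels]
        return json.dumps(payload, indent=1)


@dataclass
class NullStatArray:
    """(B+1) x m resampled statistic pairs; row 0 holds the observed pair."""

    marginal: np.ndarray
    conditional: np.ndarray
    engine: str = "glm"

    def __post_init__(self) -> None:
        self.marginal = np.atleast_2d(np.asarray(self.marginal, dtype=float))
        self.conditional = np.atleast_2d(np.asarray(self.conditional, dtype=float))
        if self.marginal.shape != self.conditional.shape:
            raise ValueError("marginal/conditional array shapes differ")
        for a in (self.marginal, self.conditional):
            if not np.all(np.isfinite(a)):
                raise ValueError("null statistics must be finite")
            if (a < 0).any():
                raise ValueError("null statistics must be non-negative")

    @property
    def B(self) -> int:
        return self.marginal.shape[0] - 1

    @property
    def m(self) -> int:
        return self.marginal.shape[1]

    @property
    def observed(self) -> StatPair:
        return StatPair(self.marginal[0], self.conditional[0], engine=self.engine)


def fit_conditional(
    X: CovariateVector,
    Z: ConfounderMatrix,
    method: str | None = None,
    spline_df: int = 4,
    residual_bootstrap: bool = False,
) -> ConditionalSampler:
    """Fit P^(X|Z) by the requested method (default chosen from X.kind:
    continuous -> gaussian_linear, binary -> logistic, categorical -> multinomial)."""
    if X.n != Z.n:
        raise ValueError("X and Z sample sizes differ")
    if method is None:
        method = _DEFAULT_METHOD[X.kind]
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    n = X.n

    if method == "permutation":
        return ConditionalSampler(method, X.kind, n, observed=np.asarray(X.values))

    if method in ("gaussian_linear", "gaussian_spline"):
        if X.kind != "continuous":
            raise ValueError(f"{method} requires a continuous covariate")
        x = np.asarray(X.values, dtype=float).ravel()
        D = _spline_or_linear_design(
            Z, spline_df if method == "gaussian_spline" else None
        )
        coef, *_ = np.linalg.lstsq(D, x, rcond=None)
        resid = x - D @ coef
        dof = max(1, n - D.shape[1])
        sd = float(np.sqrt(resid @ resid / dof))
        return ConditionalSampler(
            method, X.kind, n, design=D, coef=coef, resid_sd=sd,
            residuals=resid - resid.mean(), residual_bootstrap=residual_bootstrap,
        )

    # logistic / multinomial
    if method == "logistic" and X.kind != "binary":
        raise ValueError("logistic sampler requires a binary covariate")
    if method == "multinomial" and X.kind not in ("binary", "categorical"):
        raise ValueError("multinomial sampler requires a binary/categorical covariate")
    if X.kind == "categorical":
        levels, codes = X.levels, X.codes
    else:
        levels = np.array([0.0, 1.0])
        codes = np.asarray(X.values).astype(int)
    D = _spline_or_linear_design(Z, None)
    probs, coef = _fit_categorical_probs(D, codes, len(levels))
    return ConditionalSampler(
        method, X.kind, n, design=D, coef=coef, probs=probs, levels=levels
    )


def _fit_categorical_probs(D: np.ndarray, codes: np.ndarray, k: int):
    """ML logistic/multinomial fit of level probabilities given the Z design;
    falls back to a ridge-penalized fit when the MLE does not exist."""
    import statsmodels.api as sm
    from scipy.special import softmax

    try:
        if k == 2:
            res = sm.GLM(codes, D, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 30:
                raise ValueError("separation suspected")
            p1 = res.predict(D)
            return np.column_stack([1 - p1, p1]), res.params
        res = sm.MNLogit(codes, D).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise ValueError("separation suspected")
        return res.predict(D), res.params
    except Exception:
        logger.warning("ML fit failed/separated; falling back to ridge-penalized fit")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(D[:, 1:] if D.shape[1] > 1 else D, codes)
        probs_small = clf.predict_proba(D[:, 1:] if D.shape[1] > 1 else D)
        probs = np.zeros((D.shape[0], k))
        probs[:, clf.classes_] = probs_small
        return probs, clf.coef_


def sample_covariates(
    sampler: ConditionalSampler, B: int, seed: int
) -> list[np.ndarray]:
    """B mutually independent replicate covariate vectors from the fitted P^(X|Z)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    # salted stream: replicate noise must be independent of any data-generation
    # stream that may have been seeded with the same user integer
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A17]))
    return [sampler.sample(rng) for _ in range(B)]


def _as_covariate(values: np.ndarray, kind: str) -> CovariateVector:
    return CovariateVector(values, kind=kind)


def compute_null_stats(
    Y: FeatureMatrix,
    Z: ConfounderMatrix,
    sampler: ConditionalSampler,
    engine: str = "rv",
    B: int = 100,
    seed: int = 0,
    X_observed: CovariateVector | None = None,
    **engine_kwargs,
) -> NullStatArray:
    """Observed + B resampled statistic pairs.

    Row 0 is the pair computed on the observed covariate; rows 1..B replace X
    by replicates drawn from the sampler, everything else unchanged.  All
    randomness is consumed here (statistics themselves are deterministic).
    """
    if X_observed is None:
        raise ValueError("X_observed is required to fill row 0")
    check_alignment(Y, X_observed, Z)
    obs = compute_stat_pair(Y, X_observed, Z, engine=engine, **engine_kwargs)
    marg = np.empty((B + 1, Y.m))
    cond = np.empty((B + 1, Y.m))
    marg[0], cond[0] = obs.t_marginal, obs.t_conditional
    if B > 0:
        for b, xb in enumerate(sample_covariates(sampler, B, seed), start=1):
            pair = compute_stat_pair(
                Y, _as_covariate(xb, sampler.kind), Z, engine=engine, **engine_kwargs
            )
            marg[b], cond[b] = pair.t_marginal, pair.t_conditional
    return NullStatArray(marg, cond, engine=engine)
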