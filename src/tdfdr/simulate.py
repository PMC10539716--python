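"""Synthetic confounded-omics data and the replicated FDR/power study.

The generators emulate the standard benchmark designs for confounder-adjusted
feature screening: per-feature effects alpha_j (covariate) and beta_j
(confounder) drawn from a symmetric spike-and-slab mixture, a covariate X
entangled with the confounder Z through a tunable strength rho, and linear,
nonlinear, logistic, or Poisson outcome models.  A feature is a true signal
iff alpha_j != 0; features with alpha_j = 0 but beta_j != 0 are the
marginally-dependent nulls that make naive marginal screening invalid.

After generation X is standardized to zero mean / unit variance so that the
effect size l and the confounding strength rho can be varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ConfounderMatrix, CovariateVector, FeatureMatrix

__all__ = ["Scenario", "GeneratedDataset", "draw_coefficients", "generate", "evaluate"]

_MODELS = ("linear", "nonlinear", "logistic", "example1", "poisson")

# factor levels of the benchmark grid: rho (confounding), pi (signal density),
# l (effect size)
GRID_RHO = (0.1, 1.0, 1.5)
GRID_PI = (0.05, 0.10, 0.20)
GRID_L = (0.2, 0.3, 0.4)


@dataclass
class Scenario:
    """One simulation configuration.

    Defaults are the benchmark study conditions: n = 100 samples and m = 1000
    features, with rho in {0.1, 1, 1.5} (weak/medium/strong confounding),
    pi_signal in {0.05, 0.10, 0.20} and effect_l in {0.2, 0.3, 0.4} spanning
    the printed factor grid.
    """

    rho: float = 1.0
    pi_signal: float = 0.10
    effect_l: float = 0.3
    n: int = 100
    m: int = 1000
    outcome_model: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_model not in _MODELS:
            raise ValueError(f"unknown outcome model {self.outcome_model!r}")
        if not (0 <= self.pi_signal < 1):
            raise ValueError("pi_signal must be in [0, 1)")


@dataclass
class GeneratedDataset:
    Y: FeatureMatrix
    X: CovariateVector
    Z: ConfounderMatrix
    alpha: np.ndarray
    beta: np.ndarray

    @property
    def true_signals(self) -> np.ndarray:
        return np.nonzero(self.alpha != 0)[0]


def draw_coefficients(
    m: int, pi_signal: float, effect_l: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. draws from the spike-and-slab mixture
    (pi/2) U(-l-0.2, -l) + (pi/2) U(l, l+0.2) + (1-pi) delta_0."""
    if not (0 <= pi_signal < 1):
        raise ValueError("pi_signal must be in [0, 1)")
    if effect_l <= 0:
        raise ValueError("effect_l must be > 0")
    coefs = np.zeros(m)
    u = rng.random(m)
    neg = u < pi_signal / 2
    pos = (u >= pi_signal / 2) & (u < pi_signal)
    coefs[neg] = rng.uniform(-effect_l - 0.2, -effect_l, size=neg.sum())
    coefs[pos] = rng.uniform(effect_l, effect_l + 0.2, size=pos.sum())
    return coefs


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate(scenario: Scenario) -> GeneratedDataset:
    """One dataset from the scenario's data-generating process.

    linear     Y_j = a_j X + b_j Z + eps,          X ~ N(rho Z, 1)
    nonlinear  Y_j = a_j X^3 + b_j e^Z + eps,      X ~ N(rho Z^2, 1)
    logistic   Y_j ~ Bern(expit(a_j X + b_j Z)),   X ~ N(rho Z, 1)
    poisson    Y_j ~ Pois(exp(a_j X + b_j Z)),     X ~ N(rho Z, 1)
    example1   Y_j ~ Bern(expit(a_j X + b_j Z)),   X = (rho Z + eps)/sqrt(rho^2+1),
               coefficients from 0.15 U(-0.7,-0.5) + 0.15 U(0.5,0.7) + 0.7 delta_0

    with Z ~ N(0, 1) throughout and X standardized after generation.
    """
    sc = scenario
    # salted stream, distinct from the inference-side resampling stream
    rng = np.random.default_rng(np.random.SeedSequence([int(sc.seed), 0xDA7A]))
    z = rng.normal(size=sc.n)

    if sc.outcome_model == "example1":
        alpha = _example1_coefs(sc.m, rng)
        beta = _example1_coefs(sc.m, rng)
        x = (sc.rho * z + rng.normal(size=sc.n)) / np.sqrt(sc.rho**2 + 1)
    else:
        alpha = draw_coefficients(sc.m, sc.pi_signal, sc.effect_l, rng)
        beta = draw_coefficients(sc.m, sc.pi_signal, sc.effect_l, rng)
        if sc.outcome_model == "nonlinear":
            x = rng.normal(loc=sc.rho * z**2, scale=1.0)
        else:
            x = rng.normal(loc=sc.rho * z, scale=1.0)
    x = _standardize(x)

    if sc.outcome_model == "linear":
        eta = np.outer(x, alpha) + np.outer(z, beta)
        Yv = eta + rng.normal(size=(sc.n, sc.m))
        family = "gaussian"
    elif sc.outcome_model == "nonlinear":
        eta = np.outer(x**3, alpha) + np.outer(np.exp(z), beta)
        Yv = eta + rng.normal(size=(sc.n, sc.m))
        family = "gaussian"
    elif sc.outcome_model in ("logistic", "example1"):
        eta = np.outer(x, alpha) + np.outer(z, beta)
        Yv = rng.binomial(1, expit(eta)).astype(float)
        family = "binomial"
    else:  # poisson
        eta = np.clip(np.outer(x, alpha) + np.outer(z, beta), -20, 20)
        Yv = rng.poisson(np.exp(eta)).astype(float)
        family = "poisson"

    return GeneratedDataset(
        FeatureMatrix(Yv, outcome_family=family),
        CovariateVector(x, kind="continuous"),
        ConfounderMatrix(z[:, None]),
        alpha,
        beta,
    )


def _example1_coefs(m: int, rng: np.random.Generator) -> np.ndarray:
    """0.15 U(-0.7, -0.5) + 0.15 U(0.5, 0.7) + 0.7 delta_0."""
    coefs = np.zeros(m)
    u = rng.random(m)
    neg = u < 0.15
    pos = (u >= 0.15) & (u < 0.30)
    coefs[neg] = rng.uniform(-0.7, -0.5, size=neg.sum())
    coefs[pos] = rng.uniform(0.5, 0.7, size=pos.sum())
    return coefs


def evaluate(
    method: Callable[[GeneratedDataset, float, int], np.ndarray],
    scenario: Scenario,
    n_reps: int = 100,
    q: float = 0.05,
) -> dict:
    """Replicated empirical FDR and power of a procedure on a scenario.

    ``method(dataset, q, seed)`` must return the rejected feature indices.
    Per replicate, FDP = |rejections among nulls| / max(1, rejections) and
    power (TPP) = |rejections among signals| / max(1, #signals); means and
    standard errors of the mean over replicates are reported, along with the
    per-replicate arrays for paired comparisons.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fdps = np.zeros(n_reps)
    tpps = np.zeros(n_reps)
    nrejs = np.zeros(n_reps, dtype=int)
    for r in range(n_reps):
        sc = Scenario(
            rho=scenario.rho, pi_signal=scenario.pi_signal,
            effect_l=scenario.effect_l, n=scenario.n, m=scenario.m,
            outcome_model=scenario.outcome_model, seed=scenario.seed + r,
        )
        data = generate(sc)
        rejected = np.asarray(method(data, q, sc.seed), dtype=int)
        signals = set(data.true_signals.tolist())
        n_rej = rejected.size
        n_false = sum(1 for j in rejected if j not in signals)
        n_true = n_rej - n_false
        fdps[r] = n_false / max(1, n_rej)
        tpps[r] = n_true / max(1, len(signals))
        nrejs[r] = n_rej
    return {
        "fdr": float(fdps.mean()),
        "fdr_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)),
        "power": float(tpps.mean()),
        "power_se": float(tpps.std(ddof=1) / np.sqrt(n_reps)),
        "mean_rejections": float(nrejs.mean()),
        "fdp_per_rep": fdps,
        "tpp_per_rep": tpps,
        "n_reps": n_reps,
        "q": q,
    }


def make_procedure(
    kind: str = "2d",
    engine: str = "rv",
    B: int = 50,
    nu: int = 100,
    use_pi0: bool = True,
    **engine_kwargs,
) -> Callable[[GeneratedDataset, float, int], np.ndarray]:
    """Adapter turning the core procedures into ``evaluate``-compatible handles.

    kind: "2d" | "1d" | "fwer" | "bh_marginal" (BH on marginal-model p-values,
    the deliberately confounding-blind comparator).
    """
    from . import core

    def proc(data: GeneratedDataset, q: float, seed: int) -> np.ndarray:
        if kind == "bh_marginal":
            return _bh_marginal(data, q)
        common = dict(engine=engine, B=B, nu=nu, seed=seed, **engine_kwargs)
        if kind == "2d":
            res = core.run_2dfdr(data.Y, data.X, data.Z, q=q, use_pi0=use_pi0, **common)
        elif kind == "1d":
            res = core.run_1dfdr(data.Y, data.X, data.Z, q=q, use_pi0=use_pi0, **common)
        elif kind == "fwer":
            res = core.run_2dfwer(data.Y, data.X, data.Z, alpha=q, **common)
        else:
            raise ValueError(f"unknown procedure kind {kind!r}")
        return res.rejected

    return proc


def _bh_marginal(data: GeneratedDataset, q: float) -> np.ndarray:
    """BH applied to marginal (confounder-ignoring) GLM p-values."""
    from scipy import stats as sps

    from . import core
    from ._glm import batched_wald

    n = data.Y.n
    design = np.column_stack([np.ones(n), data.X.design()])
    stat, ok = batched_wald(design, data.Y.values, data.Y.outcome_family, slice(1, 2))
    if data.Y.outcome_family == "gaussian":
        p = 2 * sps.t.sf(stat, df=n - design.shape[1])
    else:
        p = 2 * sps.norm.sf(stat)
    p[~ok] = 1.0
    return core.bh_reference(p, q)


def benchmark_grid(
    models=("linear",),
    rhos=GRID_RHO,
    pis=GRID_PI,
    ls=GRID_L,
    n: int = 100,
    m: int = 1000,
    seed: int = 0,
) -> list[Scenario]:
    """Enumerate the factorial study grid as Scenario objects."""
    out = []
    for model in models:
        for rho in rhos:
            for pi in pis:
                for l in ls:
                    out.append(
                        Scenario(rho=rho, pi_signal=pi, effect_l=l, n=n, m=m,
                                 outcome_model=model, seed=seed)
                    )
    return out
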