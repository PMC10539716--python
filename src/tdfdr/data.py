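"""Validated in-memory containers for the feature matrix, covariate, and confounders.

Every downstream computation assumes the invariants enforced here: aligned
sample dimensions, no missing values, family-consistent outcome values, and a
full-rank confounder design after categorical encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureMatrix",
    "CovariateVector",
    "ConfounderMatrix",
    "StatPair",
]

_FAMILIES = ("gaussian", "binomial", "poisson")
_KINDS = ("continuous", "binary", "categorical")


def _as_2d(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"expected 1- or 2-d array, got shape {a.shape}")
    return a


@dataclass
class FeatureMatrix:
    """n-samples x m-features matrix of omics measurements.

    ``outcome_family`` selects the GLM family used by the model-based engine:
    gaussian (identity link), binomial (logit), or poisson (log).
    """

    values: np.ndarray
    feature_ids: list[str] | None = None
    outcome_family: str = "gaussian"

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        n, m = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.outcome_family not in _FAMILIES:
            raise ValueError(f"outcome_family must be one of {_FAMILIES}")
        if self.outcome_family == "binomial":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binomial outcomes must be coded 0/1")
        if self.outcome_family == "poisson":
            if (self.values < 0).any() or np.any(self.values != np.round(self.values)):
                raise ValueError("poisson outcomes must be non-negative integers")
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{j}" for j in range(m)]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match number of features")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateVector:
    """The covariate of interest X: a length-n vector (or n x p matrix).

    ``kind`` drives both the statistic orientation (categorical X uses a Wald
    block statistic) and the default conditional-sampler family.
    """

    values: np.ndarray
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind == "categorical":
            vals = np.asarray(self.values)
            if vals.ndim != 1:
                raise ValueError("categorical covariate must be a single column")
            self.levels, self.codes = np.unique(vals, return_inverse=True)
            if len(self.levels) < 2:
                raise ValueError("categorical covariate needs >= 2 levels")
            counts = np.bincount(self.codes)
            if (counts < 2).any():
                lev = self.levels[counts < 2]
                raise ValueError(f"categorical level(s) {lev} have < 2 samples")
            self.values = vals
        else:
            self.values = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(self.values)):
                raise ValueError("covariate contains missing/non-finite values")
            if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary covariate must be coded 0/1")

    @property
    def n(self) -> int:
        return np.asarray(self.values).shape[0]

    def design(self) -> np.ndarray:
        """Numeric design columns (no intercept): identity for numeric kinds,
        drop-first indicator contrasts for categorical."""
        if self.kind == "categorical":
            k = len(self.levels)
            out = np.zeros((self.n, k - 1))
            for lev in range(1, k):
                out[:, lev - 1] = self.codes == lev
            return out
        return _as_2d(self.values)


@dataclass
class ConfounderMatrix:
    """n x d matrix of confounders Z with per-column kinds."""

    values: np.ndarray
    kinds: list[str] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.shape[1] < 1:
            raise ValueError("need at least one confounder column")
        if self.kinds is None:
            self.kinds = ["continuous"] * vals.shape[1]
        if len(self.kinds) != vals.shape[1]:
            raise ValueError("kinds length does not match number of columns")
        for k in self.kinds:
            if k not in ("continuous", "categorical"):
                raise ValueError(f"confounder kind {k!r} invalid")
        self.values = vals
        # encode once; used by every engine and sampler
        self._encoded = self._encode()
        # a constant column carries no confounder information: drop it from the
        # encoding (no-confounder limit) instead of failing the rank check
        const = self._encoded.std(axis=0) == 0
        if const.any():
            import logging

            logging.getLogger(__name__).warning(
                "dropping %d constant confounder column(s) from the design",
                int(const.sum()),
            )
            self._encoded = self._encoded[:, ~const]
        design = np.column_stack([np.ones(self.n), self._encoded])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("confounder design is rank-deficient after encoding")

    def _encode(self) -> np.ndarray:
        cols = []
        for j, kind in enumerate(self.kinds):
            col = self.values[:, j]
            if kind == "categorical":
                levels, codes = np.unique(col, return_inverse=True)
                for lev in range(1, len(levels)):
                    cols.append((codes == lev).astype(float))
            else:
                cols.append(np.asarray(col, dtype=float))
        return np.column_stack(cols)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def design(self) -> np.ndarray:
        """Numeric design columns (no intercept)."""
        return self._encoded


@dataclass
class StatPair:
    """Per-feature marginal (T^M) and conditional (T^C) statistics.

    Both are oriented so that large positive values are evidence against the
    respective independence null.
    """

    t_marginal: np.ndarray
    t_conditional: np.ndarray
    engine: str = "glm"

    def __post_init__(self) -> None:
        self.t_marginal = np.asarray(self.t_marginal, dtype=float).ravel()
        self.t_conditional = np.asarray(self.t_conditional, dtype=float).ravel()
        if self.t_marginal.shape != self.t_conditional.shape:
            raise ValueError("marginal/conditional statistic lengths differ")
        for a in (self.t_marginal, self.t_conditional):
            if not np.all(np.isfinite(a)):
                raise ValueError("statistics must be finite")
            if (a < 0).any():
                raise ValueError("statistics must be non-negative")

    @property
    def m(self) -> int:
        return self.t_marginal.shape[0]


def check_alignment(Y: FeatureMatrix, X: CovariateVector, Z: ConfounderMatrix) -> None:
    if not (Y.n == X.n == Z.n):
        raise ValueError(
            f"sample dimensions disagree: Y has {Y.n}, X has {X.n}, Z has {Z.n}"
        )
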