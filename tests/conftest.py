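import numpy as np
import pytest

from tdfdr.data import ConfounderMatrix, CovariateVector, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear_dataset(
    n=100, m=20, rho=1.0, alpha=None, beta=None, seed=0, family="gaussian"
):
    """Small hand-rolled linear dataset with known coefficients (independent of
    the package's synthetic_data generator so it can serve as its own check)."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    x = rng.normal(loc=rho * z, scale=1.0)
    if alpha is None:
        alpha = np.zeros(m)
    if beta is None:
        beta = np.zeros(m)
    eta = np.outer(x, alpha) + np.outer(z, beta)
    if family == "gaussian":
        Yv = eta + rng.normal(size=(n, m))
    else:
        from scipy.special import expit

        Yv = rng.binomial(1, expit(eta)).astype(float)
    return (
        FeatureMatrix(Yv, outcome_family=family),
        CovariateVector(x),
        ConfounderMatrix(z[:, None]),
        np.asarray(alpha),
        np.asarray(beta),
    )


@pytest.fixture
def small_linear():
    alpha = np.array([0.8, 0.0, 0.5, 0.0, 0.0, 0.7, 0.0, 0.0, 0.4, 0.0])
    beta = np.array([0.0, 0.9, 0.5, 0.0, 0.8, 0.0, 0.0, 0.6, 0.0, 0.0])
    Y, X, Z, a, b = make_linear_dataset(n=120, m=10, rho=1.2, alpha=alpha, beta=beta, seed=7)
    return Y, X, Z, a, b
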