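"""Cutoff search, FDP estimation, and error-rate procedures, checked against
hand enumerations and exhaustive brute-force oracles."""

import numpy as np
import pytest

from tdfdr.conditional_sampler import NullStatArray
from tdfdr.core import (
    CutoffGrid,
    bh_reference,
    build_grid,
    estimate_pi0,
    fbar,
    fdp_surface,
    run_1dfdr,
    run_2dfdr,
    run_2dfwer,
    select_cutoffs,
)
from tdfdr.data import StatPair
from tdfdr.simulate import Scenario, generate

from conftest import make_linear_dataset


def random_nulls(rng, m=10, B=5):
    """A synthetic NullStatArray with continuous non-negative entries."""
    return NullStatArray(rng.random((B + 1, m)) * 3, rng.random((B + 1, m)) * 3)


# ---------------------------------------------------------------------------
# Fbar
# ---------------------------------------------------------------------------

class TestFbar:
    def test_hand_enumeration(self):
        nulls = NullStatArray(
            marginal=np.array([[2.0], [1.0], [3.0]]),
            conditional=np.array([[3.0], [4.0], [1.0]]),
        )
        assert fbar(nulls, 0, 1.5, 2.5) == pytest.approx(1 / 3)

    def test_extremes(self, rng):
        nulls = random_nulls(rng)
        assert fbar(nulls, 3, -1.0, -1.0) == 1.0
        assert fbar(nulls, 3, nulls.marginal[:, 3].max() + 1, 0.0) == 0.0

    def test_monotone_in_both_arguments(self, rng):
        nulls = random_nulls(rng, m=5, B=8)
        ts = np.linspace(0, 3, 7)
        for j in range(5):
            vals = np.array([[fbar(nulls, j, t1, t2) for t2 in ts] for t1 in ts])
            assert (np.diff(vals, axis=0) <= 0).all()
            assert (np.diff(vals, axis=1) <= 0).all()


# ---------------------------------------------------------------------------
# pi0
# ---------------------------------------------------------------------------

class TestEstimatePi0:
    def test_saturation_at_large_lambda(self, rng):
        nulls = random_nulls(rng)
        assert estimate_pi0(nulls, 10.0) == 1.0

    def test_empty_denominator_returns_one(self, rng):
        nulls = random_nulls(rng)
        assert estimate_pi0(nulls, -1.0) == 1.0

    def test_global_null_close_to_one(self):
        # pure-null statistics: pi0 should sit in [0.9, 1] on average
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            nulls = NullStatArray(
                np.abs(r.normal(size=(31, 300))), np.abs(r.normal(size=(31, 300)))
            )
            lam = float(np.median(nulls.conditional[1:]))
            vals.append(estimate_pi0(nulls, lam))
        assert 0.9 <= np.mean(vals) <= 1.0

    def test_half_strong_signals_estimates_half(self):
        # 50% of features carry a clearly separated alternative
        r = np.random.default_rng(5)
        m, B = 1000, 50
        cond = np.abs(r.normal(size=(B + 1, m)))
        cond[0, : m // 2] = 10.0  # strong observed signals
        nulls = NullStatArray(np.abs(r.normal(size=(B + 1, m))), cond)
        lam = float(np.median(nulls.conditional[1:]))
        assert estimate_pi0(nulls, lam) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------------------
# FDP surface and cutoff selection vs brute force
# ---------------------------------------------------------------------------

def brute_force_surface(stats, nulls, grid, pi0):
    A, C = grid.s1.size, grid.s2.size
    m, B = nulls.m, nulls.B
    fdp = np.zeros((A, C))
    rej = np.zeros((A, C), dtype=int)
    for a in range(A):
        for c in range(C):
            t1, t2 = grid.s1[a], grid.s2[c]
            num = 0.0
            for j in range(m):
                hits = 0
                for b in range(B + 1):
                    if nulls.marginal[b, j] >= t1 and nulls.conditional[b, j] >= t2:
                        hits += 1
                num += hits / (B + 1)
            nrej = int(
                ((stats.t_marginal >= t1) & (stats.t_conditional >= t2)).sum()
            )
            rej[a, c] = nrej
            fdp[a, c] = pi0 * num / max(1, nrej)
    return fdp, rej


def brute_force_select(fdp, rej, grid, q):
    best = None
    for a in range(grid.s1.size):
        for c in range(grid.s2.size):
            if fdp[a, c] > q:
                continue
            key = (rej[a, c], -fdp[a, c], grid.s2[c], grid.s1[a])
            if best is None or key > best[0]:
                best = (key, a, c)
    return best


class TestFdpSurfaceOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_exactly(self, seed):
        r = np.random.default_rng(seed)
        nulls = random_nulls(r, m=10, B=5)
        stats = nulls.observed
        grid = build_grid(stats, nu=7)
        surf = fdp_surface(stats, nulls, grid, use_pi0=True)
        fdp_bf, rej_bf = brute_force_surface(stats, nulls, grid, surf.pi0)
        np.testing.assert_array_equal(surf.rejections, rej_bf)
        np.testing.assert_allclose(surf.fdp, fdp_bf, atol=1e-12)

    def test_sentinel_column_equals_1d_estimator(self, rng):
        nulls = random_nulls(rng, m=15, B=8)
        stats = nulls.observed
        grid = build_grid(stats, nu=6)
        surf = fdp_surface(stats, nulls, grid, use_pi0=False)
        # row 0 of the surface is the no-screening (1D) estimator over t2
        for c, t2 in enumerate(grid.s2):
            num = sum(
                fbar(nulls, j, -np.inf, t2) for j in range(nulls.m)
            )
            nrej = int((stats.t_conditional >= t2).sum())
            assert surf.fdp[0, c] == pytest.approx(num / max(1, nrej), abs=1e-12)

    def test_rejections_monotone_in_both_cutoffs(self, rng):
        nulls = random_nulls(rng, m=20, B=6)
        stats = nulls.observed
        grid = build_grid(stats, nu=10)
        surf = fdp_surface(stats, nulls, grid)
        assert (np.diff(surf.rejections, axis=0) <= 0).all()
        assert (np.diff(surf.rejections, axis=1) <= 0).all()

    def test_self_inclusion_floor_with_rejections(self, rng):
        nulls = random_nulls(rng, m=12, B=4)
        stats = nulls.observed
        grid = build_grid(stats, nu=8)
        surf = fdp_surface(stats, nulls, grid, use_pi0=False)
        has_rej = surf.rejections >= 1
        # each rejected feature contributes its own b=0 indicator to Fbar
        assert (
            surf.fdp[has_rej] >= 1 / (nulls.B + 1) / np.maximum(1, surf.rejections[has_rej]) - 1e-12
        ).all()


class TestSelectCutoffs:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        r = np.random.default_rng(100 + seed)
        m = int(r.integers(5, 21))
        B = int(r.integers(2, 11))
        nu = int(r.integers(3, 11))
        nulls = random_nulls(r, m=m, B=B)
        stats = nulls.observed
        grid = build_grid(stats, nu=nu)
        surf = fdp_surface(stats, nulls, grid)
        q = float(r.uniform(0.05, 0.5))
        res = select_cutoffs(surf, grid, q, stats)
        best = brute_force_select(surf.fdp, surf.rejections, grid, q)
        if best is None:
            assert res.n_rejections == 0 and np.isinf(res.t1_star)
        else:
            _, a, c = best
            assert res.t1_star == grid.s1[a]
            assert res.t2_star == grid.s2[c]
            assert res.n_rejections == surf.rejections[a, c]

    def test_q_below_resolution_floor_rejects_nothing(self, rng):
        nulls = random_nulls(rng, m=10, B=5)
        stats = nulls.observed
        grid = build_grid(stats, nu=10)
        surf = fdp_surface(stats, nulls, grid, use_pi0=False)
        res = select_cutoffs(surf, grid, q=1 / (nulls.B + 1) / 20, stats=stats)
        assert res.n_rejections == 0

    def test_q_one_rejects_everything(self, rng):
        nulls = random_nulls(rng, m=10, B=5)
        stats = nulls.observed
        grid = build_grid(stats, nu=10)
        surf = fdp_surface(stats, nulls, grid, use_pi0=False)
        res = select_cutoffs(surf, grid, q=1.0, stats=stats)
        assert res.n_rejections == nulls.m

    def test_rejected_set_consistent_with_cutoffs(self, rng):
        nulls = random_nulls(rng, m=25, B=6)
        stats = nulls.observed
        grid = build_grid(stats, nu=8)
        surf = fdp_surface(stats, nulls, grid)
        res = select_cutoffs(surf, grid, 0.3, stats)
        for j in res.rejected:
            assert stats.t_marginal[j] >= res.t1_star
            assert stats.t_conditional[j] >= res.t2_star
        assert res.fdp_at_optimum <= 0.3


# ---------------------------------------------------------------------------
# end-to-end procedures
# ---------------------------------------------------------------------------

class TestProcedures:
    def test_2d_dominates_1d_across_models(self):
        for i, model in enumerate(["linear", "nonlinear", "logistic"]):
            engine = "glm" if model == "logistic" else "rv"
            sampler = "gaussian_spline" if model == "nonlinear" else None
            for seed in range(3):
                d = generate(Scenario(rho=1.2, pi_signal=0.15, effect_l=0.4, n=80,
                                      m=100, outcome_model=model, seed=10 * i + seed))
                kw = dict(engine=engine, sampler_method=sampler, q=0.1, B=30,
                          nu=50, seed=seed)
                r2 = run_2dfdr(d.Y, d.X, d.Z, **kw)
                r1 = run_1dfdr(d.Y, d.X, d.Z, **kw)
                assert r2.n_rejections >= r1.n_rejections

    def test_1d_equals_sentinel_column_restriction(self, small_linear):
        Y, X, Z, *_ = small_linear
        kw = dict(engine="rv", q=0.2, B=20, nu=10, seed=3)
        r1 = run_1dfdr(Y, X, Z, **kw)
        r2 = run_2dfdr(Y, X, Z, **kw)
        # the 1D surface is the sentinel column of the 2D surface
        np.testing.assert_allclose(r1.surface.fdp[0], r2.surface.fdp[0], atol=1e-12)
        assert r1.t1_star in (r2.grid.s1[0], np.inf)

    def test_single_feature_reduces_to_joint_bootstrap_test(self):
        rng = np.random.default_rng(31)
        n = 80
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n)
        y = 0.9 * x + rng.normal(size=n)
        from tdfdr.data import ConfounderMatrix, CovariateVector, FeatureMatrix

        Y = FeatureMatrix(y[:, None])
        res = run_2dfdr(Y, CovariateVector(x), ConfounderMatrix(z[:, None]),
                        engine="rv", q=0.05, B=99, seed=4)
        nulls, stats = res.nulls, res.stats
        joint_p = res.pi0 * fbar(nulls, 0, stats.t_marginal[0], stats.t_conditional[0])
        assert (res.n_rejections == 1) == (joint_p <= 0.05)

    def test_deterministic_given_seed(self, small_linear):
        Y, X, Z, *_ = small_linear
        a = run_2dfdr(Y, X, Z, engine="rv", q=0.1, B=25, seed=9)
        b = run_2dfdr(Y, X, Z, engine="rv", q=0.1, B=25, seed=9)
        np.testing.assert_array_equal(a.rejected, b.rejected)
        assert a.t1_star == b.t1_star and a.t2_star == b.t2_star

    def test_constant_features_dropped_not_rejected(self):
        Y, X, Z, *_ = make_linear_dataset(n=60, m=8, rho=0.5,
                                          alpha=np.full(8, 0.9), seed=2)
        from tdfdr.data import FeatureMatrix

        vals = Y.values.copy()
        vals[:, 4] = 1.0
        Yc = FeatureMatrix(vals)
        res = run_2dfdr(Yc, X, Z, engine="rv", q=0.2, B=20, seed=1)
        assert 4 not in res.rejected
        assert 4 in res.dropped_features

    def test_empty_matrix_returns_empty_result(self):
        import dataclasses

        from tdfdr.data import ConfounderMatrix, CovariateVector, FeatureMatrix

        rng = np.random.default_rng(0)
        Y = FeatureMatrix(rng.normal(size=(10, 1)))
        Ym0 = dataclasses.replace(Y)
        Ym0.values = Y.values[:, :0]
        Ym0.feature_ids = []
        res = run_2dfdr(Ym0, CovariateVector(rng.normal(size=10)),
                        ConfounderMatrix(rng.normal(size=(10, 1))))
        assert res.n_rejections == 0


class TestFwer:
    def test_matches_brute_force_calibrated_estimator(self, small_linear):
        """The FWER surface is the any-hit fraction over all B+1 rows, and the
        selection maximizes rejections at the search-calibrated working level
        (largest level at which at most floor(alpha*(B+1)) rows would reject)."""
        Y, X, Z, *_ = small_linear
        alpha = 0.3
        res = run_2dfwer(Y, X, Z, engine="rv", alpha=alpha, B=20, nu=10, seed=2)
        nulls, grid = res.nulls, res.grid
        B = nulls.B
        est = np.empty((grid.s1.size, grid.s2.size))
        for a, t1 in enumerate(grid.s1):
            for c, t2 in enumerate(grid.s2):
                est[a, c] = np.mean([
                    ((nulls.marginal[b] >= t1) & (nulls.conditional[b] >= t2)).any()
                    for b in range(B + 1)
                ])
                assert res.surface.fdp[a, c] == pytest.approx(est[a, c], abs=1e-12)
        # per-row cheapest rejecting cell, then the calibrated working level
        e = np.full(B + 1, np.inf)
        for r in range(B + 1):
            for a, t1 in enumerate(grid.s1):
                for c, t2 in enumerate(grid.s2):
                    if ((nulls.marginal[r] >= t1) & (nulls.conditional[r] >= t2)).any():
                        e[r] = min(e[r], est[a, c])
        n_ok = np.floor(alpha * (B + 1))
        feas = [v for v in np.sort(e[np.isfinite(e)]) if (e <= v).sum() <= n_ok]
        if not feas:
            assert res.n_rejections == 0
        else:
            alpha_work = max(feas)
            assert res.params["alpha_work"] == pytest.approx(alpha_work, abs=1e-12)
            best = 0
            for a, t1 in enumerate(grid.s1):
                for c, t2 in enumerate(grid.s2):
                    if est[a, c] <= alpha_work:
                        best = max(best, int(((nulls.marginal[0] >= t1)
                                              & (nulls.conditional[0] >= t2)).sum()))
            assert res.n_rejections == best
            assert res.fdp_at_optimum <= alpha

    def test_fwer_no_more_rejections_than_fdr(self):
        for seed in range(6):
            alpha = np.zeros(40)
            alpha[:8] = 0.8
            Y, X, Z, *_ = make_linear_dataset(n=80, m=40, rho=1.0, alpha=alpha,
                                              seed=50 + seed)
            rfwer = run_2dfwer(Y, X, Z, engine="rv", alpha=0.1, B=30, nu=20, seed=seed)
            rfdr = run_2dfdr(Y, X, Z, engine="rv", q=0.1, B=30, nu=20, seed=seed)
            assert rfwer.n_rejections <= rfdr.n_rejections


class TestExceedanceCounting:
    """The histogram/suffix-sum counting must agree with direct comparison
    for arbitrary non-negative inputs, including ties with grid values."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(np.float64, (7, 4),
               elements=st.floats(0, 5, allow_nan=False).map(lambda v: round(v, 1))),
        arrays(np.float64, (7, 4),
               elements=st.floats(0, 5, allow_nan=False).map(lambda v: round(v, 1))),
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_match_direct_comparison(self, vm, vc):
        from tdfdr.core import _exceedance_counts

        s1 = np.unique(np.concatenate([[0.0], vm.ravel()[:5]]))
        s2 = np.unique(vc.ravel()[:5])
        counts = _exceedance_counts(vm, vc, s1, s2)
        for a, t1 in enumerate(s1):
            for c, t2 in enumerate(s2):
                direct = int(((vm >= t1) & (vc >= t2)).sum())
                assert counts[a, c] == direct


class TestBhReference:
    def test_hand_step_up(self):
        assert set(bh_reference(np.array([0.001, 0.02, 0.9]), 0.05)) == {0, 1}

    def test_all_ones_empty(self):
        assert bh_reference(np.ones(5), 0.05).size == 0

    def test_single_pvalue(self):
        assert set(bh_reference(np.array([0.04]), 0.05)) == {0}
        assert bh_reference(np.array([0.06]), 0.05).size == 0

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_reference(np.array([0.5, 1.2]), 0.05)
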