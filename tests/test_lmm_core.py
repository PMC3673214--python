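"""Core REML machinery checked against a dense-covariance oracle.

The oracle builds the full n x n covariance X X' + delta I, Cholesky-factors
it, and evaluates the textbook restricted likelihood; the implementation
must agree through its low-rank path to high precision.
"""

import numpy as np
import pytest

from lmmset.lmm_core import (KernelFactor, TwoKernelWorkspace, fit_two_kernel,
                             lrt_statistic, reml_profile, stacked_factor)


def dense_reml_oracle(y, F, X, delta):
    """Textbook REML loglik via dense Cholesky; independent of the package path."""
    n, p = F.shape
    Sig = X @ X.T + delta * np.eye(n)
    L = np.linalg.cholesky(Sig)
    Si_y = np.linalg.solve(Sig, y)
    Si_F = np.linalg.solve(Sig, F)
    A = F.T @ Si_F
    beta = np.linalg.solve(A, F.T @ Si_y)
    r2 = y @ Si_y - (F.T @ Si_y) @ beta
    sg2 = r2 / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sg2)
        + 2 * np.log(np.diag(L)).sum()
        + np.linalg.slogdet(A)[1]
        - np.linalg.slogdet(F.T @ F)[1]
        + (n - p)
    )
    return ll, beta, sg2


def random_instance(rng, n=None, kw=None, kv=None, p=None):
    n = n or int(rng.integers(30, 200))
    kw = kw if kw is not None else int(rng.integers(0, 20))
    kv = kv if kv is not None else int(rng.integers(1, 10))
    p = p or int(rng.integers(1, 4))
    W = KernelFactor(rng.standard_normal((n, kw)), float(max(kw, 1)))
    V = KernelFactor(rng.standard_normal((n, kv)), float(kv))
    F = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    return y, F, W, V


class TestStackedFactor:
    def test_tau_zero_is_confounder_kernel(self, rng):
        y, F, W, V = random_instance(rng, n=40)
        X = stacked_factor(W, V, 0.0)
        np.testing.assert_allclose(X @ X.T, W.factor @ W.factor.T / W.scale,
                                   atol=1e-12)

    def test_tau_one_is_set_kernel(self, rng):
        y, F, W, V = random_instance(rng, n=40)
        X = stacked_factor(W, V, 1.0)
        np.testing.assert_allclose(X @ X.T, V.factor @ V.factor.T / V.scale,
                                   atol=1e-12)

    def test_convex_combination(self, rng):
        W = KernelFactor(rng.standard_normal((50, 5)), 5.0)
        V = KernelFactor(rng.standard_normal((50, 3)), 3.0)
        X = stacked_factor(W, V, 0.3)
        K = 0.7 * W.factor @ W.factor.T / 5 + 0.3 * V.factor @ V.factor.T / 3
        assert np.abs(X @ X.T - K).max() < 1e-10

    def test_mismatched_n(self, rng):
        W = KernelFactor(rng.standard_normal((50, 5)), 5.0)
        V = KernelFactor(rng.standard_normal((40, 3)), 3.0)
        with pytest.raises(ValueError, match="mismatch"):
            stacked_factor(W, V, 0.5)

    def test_tau_outside_box(self, rng):
        y, F, W, V = random_instance(rng, n=30)
        with pytest.raises(ValueError):
            stacked_factor(W, V, 1.5)


class TestRemlProfile:
    @pytest.mark.parametrize("delta", [0.1, 1.0, 10.0])
    def test_matches_dense_oracle(self, rng, delta):
        for _ in range(10):
            y, F, W, V = random_instance(rng)
            for tau in (0.0, 0.3, 1.0):
                X = stacked_factor(W, V, tau)
                ll, beta, sg2 = reml_profile(y, F, X, delta)
                llo, betao, sg2o = dense_reml_oracle(y, F, X, delta)
                assert abs(ll - llo) < 1e-6
                np.testing.assert_allclose(beta, betao, atol=1e-8)

    def test_workspace_agrees_with_svd_path(self, rng):
        y, F, W, V = random_instance(rng, n=120, kw=12, kv=5)
        ws = TwoKernelWorkspace(y, F, W, V)
        for tau in (0.0, 0.42, 1.0):
            for delta in (0.5, 2.0):
                ll_ws = ws.profile(tau).eval(delta)[0]
                ll_svd = reml_profile(y, F, stacked_factor(W, V, tau), delta)[0]
                assert abs(ll_ws - ll_svd) < 1e-8

    def test_empty_factor_is_ols_reml(self, rng):
        """k = 0 reduces to the closed-form OLS restricted likelihood."""
        n, p = 60, 2
        F = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p - 1))])
        y = rng.standard_normal(n)
        X = np.zeros((n, 0))
        beta_ols = np.linalg.lstsq(F, y, rcond=None)[0]
        rss = float(((y - F @ beta_ols) ** 2).sum())
        s2 = rss / (n - p)
        ll_ols = -0.5 * ((n - p) * np.log(2 * np.pi * s2) + (n - p))
        for delta in (0.1, 1.0, 10.0):
            ll, beta, _ = reml_profile(y, F, X, delta)
            assert abs(ll - ll_ols) < 1e-8  # delta-invariant without genetics
            np.testing.assert_allclose(beta, beta_ols, atol=1e-8)

    def test_nonpositive_delta_rejected(self, rng):
        y, F, W, V = random_instance(rng, n=30)
        with pytest.raises(ValueError, match="delta"):
            reml_profile(y, F, stacked_factor(W, V, 0.5), 0.0)

    def test_collinear_fixed_effects_named(self, rng):
        n = 30
        F = np.ones((n, 2))  # duplicated intercept
        y = rng.standard_normal(n)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            reml_profile(y, F, np.zeros((n, 0)), 1.0)

    def test_shift_invariance_with_intercept(self, rng):
        """Adding a constant to y leaves the restricted likelihood unchanged."""
        y, F, W, V = random_instance(rng, n=80, kw=6, kv=3, p=2)
        X = stacked_factor(W, V, 0.4)
        ll1 = reml_profile(y, F, X, 1.3)[0]
        ll2 = reml_profile(y + 57.0, F, X, 1.3)[0]
        assert abs(ll1 - ll2) < 1e-6


class TestFitTwoKernel:
    def test_null_fit_is_single_kernel_fit(self, rng):
        y, F, W, V = random_instance(rng, n=100, kw=8, kv=4)
        fit0 = fit_two_kernel(y, F, W, V, tau_fixed=0.0)
        solo = fit_two_kernel(y, F, W, KernelFactor.empty(100), tau_fixed=0.0)
        assert abs(fit0.reml_loglik - solo.reml_loglik) < 1e-8
        assert abs(fit0.delta - solo.delta) < 1e-4

    def test_identical_kernels_flat_in_tau(self, rng):
        n = 80
        Z = rng.standard_normal((n, 6))
        W = KernelFactor(Z, 6.0)
        V = KernelFactor(Z.copy(), 6.0)
        F = np.ones((n, 1))
        y = rng.standard_normal(n) + Z @ rng.standard_normal(6) * 0.3
        alt = fit_two_kernel(y, F, W, V)
        null = fit_two_kernel(y, F, W, V, tau_fixed=0.0)
        assert abs(alt.reml_loglik - null.reml_loglik) < 1e-6

    def test_alternative_never_below_null(self, rng):
        """Nesting: maximized alt likelihood >= null likelihood, always."""
        for _ in range(15):
            y, F, W, V = random_instance(rng)
            alt = fit_two_kernel(y, F, W, V)
            null = fit_two_kernel(y, F, W, V, tau_fixed=0.0)
            assert alt.reml_loglik >= null.reml_loglik - 1e-7

    def test_strong_set_effect_detected(self, rng):
        """A set explaining ~20% of variance yields a large statistic."""
        hits = 0
        for rep in range(7):
            r = np.random.default_rng(1000 + rep)
            n, kv = 500, 5
            Zv = r.standard_normal((n, kv))
            Zw = r.standard_normal((n, 15))
            y = (np.sqrt(0.2 / kv) * Zv @ r.standard_normal(kv)
                 + np.sqrt(0.8) * r.standard_normal(n))
            W, V = KernelFactor(Zw, 15.0), KernelFactor(Zv, float(kv))
            F = np.ones((n, 1))
            stat = lrt_statistic(fit_two_kernel(y, F, W, V),
                                 fit_two_kernel(y, F, W, V, tau_fixed=0.0))
            hits += stat > 10
        assert hits >= 4

    def test_null_data_tau_often_zero(self):
        """With background signal in W and none in V, tau-hat sits at or near
        the boundary in the majority of replicates."""
        at_boundary = 0
        for rep in range(20):
            r = np.random.default_rng(2000 + rep)
            n = 200
            Zw = r.standard_normal((n, 10))
            W = KernelFactor(Zw, 10.0)
            V = KernelFactor(r.standard_normal((n, 4)), 4.0)
            y = (np.sqrt(0.4 / 10) * Zw @ r.standard_normal(10)
                 + np.sqrt(0.6) * r.standard_normal(n))
            fit = fit_two_kernel(y, np.ones((n, 1)), W, V)
            at_boundary += fit.tau < 0.05
        assert at_boundary >= 12

    def test_permutation_invariance(self, rng):
        """Jointly permuting individuals leaves the LRT unchanged."""
        y, F, W, V = random_instance(rng, n=90, kw=7, kv=3, p=2)
        perm = rng.permutation(90)
        stat = lrt_statistic(fit_two_kernel(y, F, W, V),
                             fit_two_kernel(y, F, W, V, tau_fixed=0.0))
        Wp = KernelFactor(W.factor[perm], W.scale)
        Vp = KernelFactor(V.factor[perm], V.scale)
        stat_p = lrt_statistic(fit_two_kernel(y[perm], F[perm], Wp, Vp),
                               fit_two_kernel(y[perm], F[perm], Wp, Vp,
                                              tau_fixed=0.0))
        assert abs(stat - stat_p) < 1e-5


class TestLrtStatistic:
    def test_equal_fits_give_zero(self, rng):
        y, F, W, V = random_instance(rng, n=50)
        fit = fit_two_kernel(y, F, W, V, tau_fixed=0.0)
        assert lrt_statistic(fit, fit) == 0.0

    def test_boundary_tau_gives_zero(self, rng):
        y, F, W, V = random_instance(rng, n=50)
        null = fit_two_kernel(y, F, W, V, tau_fixed=0.0)
        alt = fit_two_kernel(y, F, W, V)
        if alt.tau == 0.0:
            assert lrt_statistic(alt, null) == 0.0
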