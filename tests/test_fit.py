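import numpy as np
import pytest
from scipy.special import expit, logit

from curegee import (
    FitControl,
    SimConfig,
    fit,
    posterior_uncured_weight,
    simulate_dataset,
    solve_incidence_gee,
    solve_latency_gee,
)


class TestPosteriorWeight:
    def test_event_forces_uncured(self, rng):
        pi = rng.uniform(0.05, 0.95, 20)
        S = rng.uniform(0, 1, 20)
        g = posterior_uncured_weight(pi, S, np.ones(20, dtype=int))
        np.testing.assert_array_equal(g, 1.0)

    def test_direct_substitution(self):
        assert posterior_uncured_weight(0.5, 0.5, 0) == pytest.approx(1 / 3)

    def test_beyond_tail_censored_classified_cured(self):
        assert posterior_uncured_weight(0.9, 0.0, 0) == 0.0

    def test_bounds_and_monotonicity_in_survival(self, rng):
        pi = 0.7
        S = np.sort(rng.uniform(0, 1, 50))
        g = posterior_uncured_weight(pi, S, np.zeros(50, dtype=int))
        assert np.all((g >= 0) & (g <= 1))
        assert np.all(np.diff(g) >= 0)


def _groups_for(n_clusters, size):
    idx = np.arange(n_clusters * size).reshape(n_clusters, size)
    return {size: idx}


class TestIncidenceGEE:
    def test_matches_logistic_mle_under_independence(self, rng):
        # oracle: statsmodels maximum-likelihood logistic regression; with
        # binary responses and the identity working matrix the score
        # equations coincide
        import statsmodels.api as sm

        N = 150
        Z = rng.normal(size=(N, 2))
        y = (rng.uniform(size=N) < expit(0.4 + Z @ [0.8, -0.5])).astype(float)
        groups = _groups_for(50, 3)
        gamma = solve_incidence_gee(y, Z, groups, "independent", tol=1e-10)
        mle = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        np.testing.assert_allclose(gamma, mle.params, atol=1e-6)

    def test_intercept_only_closed_form(self):
        g = np.full(30, 0.3)
        Z = np.empty((30, 0))
        gamma = solve_incidence_gee(g, Z, _groups_for(10, 3), "independent", tol=1e-12)
        assert gamma[0] == pytest.approx(logit(0.3), abs=1e-8)

    def test_fractional_responses_supported(self, rng):
        N = 90
        Z = rng.normal(size=(N, 1))
        g = rng.uniform(0.05, 0.95, N)
        gamma = solve_incidence_gee(g, Z, _groups_for(30, 3), "exchangeable", rho=0.3)
        assert np.all(np.isfinite(gamma))

    def test_separation_raises(self):
        Z = np.linspace(-1, 1, 30)[:, None]
        y = (Z[:, 0] > 0).astype(float)
        from curegee.fit import ConvergenceError

        with pytest.raises(ConvergenceError):
            solve_incidence_gee(y, Z, _groups_for(10, 3), "independent", max_iter=200)


class TestLatencyGEE:
    def test_matches_centered_wls_under_independence(self, rng):
        # closed-form oracle: with g = 1 and identity working matrix the
        # root is the least-squares fit of y on centered X
        N = 120
        X = rng.normal(size=(N, 2))
        y = X @ [0.6, 0.9] + rng.normal(size=N)
        groups = _groups_for(40, 3)
        beta = solve_latency_gee(np.ones(N), y, X, groups, "independent")
        Xc = X - X.mean(axis=0)
        oracle = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_scalar_b_matrix_cancels(self, rng):
        N = 60
        X = rng.normal(size=(N, 2))
        y = X @ [1.0, -0.3] + rng.normal(size=N)
        g = rng.uniform(0.2, 1.0, N)
        groups = _groups_for(20, 3)
        b1 = solve_latency_gee(g, y, X, groups, "exchangeable", rho=0.4, phi=2.0, B_scale=1.0)
        b2 = solve_latency_gee(g, y, X, groups, "exchangeable", rho=0.4, phi=2.0, B_scale=37.5)
        np.testing.assert_allclose(b1, b2, rtol=1e-12)

    def test_matches_dense_linear_solve(self, rng):
        # oracle: assemble the full estimating equation densely per cluster
        N, n = 30, 3
        X = rng.normal(size=(N, 2))
        y = rng.normal(size=N)
        g = rng.uniform(0.1, 1.0, N)
        rho, phi = 0.35, 1.7
        groups = _groups_for(10, n)
        beta = solve_latency_gee(g, y, X, groups, "exchangeable", rho=rho, phi=phi)
        from curegee import build_working_matrix

        Qinv = np.linalg.inv(build_working_matrix("exchangeable", rho, n))
        xbar = X.mean(axis=0)
        A = np.zeros((2, 2)); b = np.zeros(2)
        for rows in groups[n]:
            Xi, yi, Gi = X[rows], y[rows], np.diag(g[rows])
            Xci = Xi - xbar
            A += Xci.T @ (Qinv / phi) @ Gi @ Xi
            b += Xci.T @ (Qinv / phi) @ Gi @ yi
        np.testing.assert_allclose(beta, np.linalg.solve(A, b), rtol=1e-10)


class TestFit:
    def test_weights_valid_and_events_forced(self, medium_dataset):
        res = fit(medium_dataset, "exchangeable", "exchangeable")
        g = res.weights
        assert np.all((g >= 0) & (g <= 1))
        np.testing.assert_array_equal(g[medium_dataset.event == 1], 1.0)

    def test_converged_flag_reflects_tolerance(self, medium_dataset):
        res = fit(medium_dataset, "independent", "independent")
        assert res.converged
        assert res.trace[-1]["diff"] < FitControl().em_tol

    def test_independent_never_estimates_rho(self, medium_dataset, monkeypatch):
        import sys

        fit_mod = sys.modules["curegee.fit"]

        calls = []

        def spy(*args, **kwargs):
            calls.append(1)
            raise AssertionError("estimate_rho called under independent structure")

        monkeypatch.setattr(fit_mod, "estimate_rho", spy)
        res = fit(medium_dataset, "independent", "independent")
        assert not calls
        assert res.corr_incidence.rho == 0.0 and res.corr_incidence.phi == 1.0

    def test_independent_vs_exchangeable_agree_without_correlation(self, independent_dataset):
        # at true zero correlation rho_hat ~ 0 and Q is near identity, so
        # the two working structures give nearly identical estimates
        a = fit(independent_dataset, "independent", "independent")
        b = fit(independent_dataset, "exchangeable", "exchangeable")
        assert abs(b.corr_incidence.rho) < 0.1
        np.testing.assert_allclose(a.gamma, b.gamma, atol=0.05)
        np.testing.assert_allclose(a.beta, b.beta, atol=0.05)

    def test_cluster_relabeling_leaves_fit_unchanged(self, medium_dataset):
        from curegee import ClusteredDataset

        relabeled = ClusteredDataset(
            cluster_id=np.array([f"site-{c}" for c in medium_dataset.cluster_id]),
            time=medium_dataset.time,
            event=medium_dataset.event,
            Z=medium_dataset.Z,
            X=medium_dataset.X,
        )
        a = fit(medium_dataset, "exchangeable", "exchangeable")
        b = fit(relabeled, "exchangeable", "exchangeable")
        np.testing.assert_allclose(a.gamma, b.gamma, rtol=1e-12)
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-12)

    def test_no_events_rejected(self):
        from curegee import ClusteredDataset

        ds = ClusteredDataset(
            cluster_id=np.repeat([0, 1], 3), time=np.ones(6), event=np.zeros(6),
            Z=np.zeros((6, 1)), X=np.zeros((6, 1)),
        )
        with pytest.raises(ValueError, match="no observed events"):
            fit(ds)

    def test_unequal_cluster_sizes_supported(self):
        cfg = SimConfig(K=40, n=[2, 3, 4, 5] * 10, zeta=0.2, tau=0.4)
        ds = simulate_dataset(cfg, seed=5)
        res = fit(ds, "exchangeable", "ar1")
        assert res.converged
        assert np.isfinite(res.gamma).all() and np.isfinite(res.beta).all()

    def test_parameter_recovery_at_independence(self):
        # Monte Carlo consistency: K = 400 clusters, no within-cluster
        # association, 200 replications; mean estimates within 3 MC se of
        # the generating values
        cfg = SimConfig(K=400, n=3, zeta=0.0, tau=0.0, gamma=(-0.3, 0.6, 0.9))
        draws = []
        for r in range(200):
            ds = simulate_dataset(cfg, seed=3000 + r)
            res = fit(ds, "independent", "independent")
            draws.append(np.concatenate([res.gamma, res.beta]))
        draws = np.asarray(draws)
        truth = np.array([-0.3, 0.6, 0.9, 0.6, 0.9])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - truth), 3 * se)
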