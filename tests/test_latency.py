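import numpy as np
import pytest

from curegee import (
    ClusteredDataset,
    ResidualSet,
    StepSurvival,
    compute_residuals,
    estimate_error_survival,
    impute_log_response,
)


def _dataset(times, events, X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    return ClusteredDataset(
        cluster_id=np.zeros(len(times)), time=np.asarray(times, dtype=float),
        event=np.asarray(events), Z=X.copy(), X=X,
    )


class TestResiduals:
    def test_zero_beta_gives_log_times(self, rng):
        t = rng.uniform(0.5, 4.0, 10)
        ds = _dataset(t, np.ones(10), rng.normal(size=(10, 2)))
        res = compute_residuals(np.zeros(2), ds)
        np.testing.assert_allclose(res.eps, np.log(t))

    def test_forced_identity_gives_zero_residuals(self, rng):
        X = rng.normal(size=(8, 2))
        beta = np.array([0.4, -1.1])
        ds = _dataset(np.exp(X @ beta), np.ones(8), X)
        res = compute_residuals(beta, ds)
        np.testing.assert_allclose(res.eps, 0.0, atol=1e-12)

    def test_matches_elementwise_recomputation(self, rng):
        X = rng.normal(size=(15, 3))
        beta = rng.normal(size=3)
        t = rng.uniform(0.1, 9.0, 15)
        ds = _dataset(t, rng.integers(0, 2, 15) | 1, X)
        res = compute_residuals(beta, ds)
        for i in range(15):
            assert res.eps[i] == pytest.approx(np.log(t[i]) - beta @ X[i])

    def test_wrong_beta_length_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="beta"):
            compute_residuals(np.zeros(3), tiny_dataset)


class TestStepSurvival:
    def test_evaluation_rules(self):
        S = StepSurvival(knots=[0.0, 1.0], values=[0.6, 0.2])
        assert S(-5.0) == 1.0          # before the first knot
        assert S(0.0) == 1.0           # sum over knots strictly below y
        assert S(0.5) == pytest.approx(0.6)
        assert S(1.0) == pytest.approx(0.6)
        assert S(1.0 + 1e-12) == 0.0   # zero beyond the last knot

    def test_masses_sum_to_one_with_zero_tail(self):
        S = StepSurvival(knots=[0.0, 1.0, 2.0], values=[0.5, 0.3, 0.1])
        m = S.masses()
        assert m.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(m, [0.5, 0.2, 0.3])  # last knot absorbs the tail

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            StepSurvival(knots=[1.0, 0.5], values=[0.5, 0.2])
        with pytest.raises(ValueError):
            StepSurvival(knots=[0.0, 1.0], values=[0.2, 0.5])


class TestErrorSurvival:
    def test_single_uncensored_residual(self):
        res = ResidualSet(eps=np.array([0.7]), delta=np.array([1]), g=np.array([1.0]))
        S = estimate_error_survival(res)
        assert S(0.7) == pytest.approx(1.0)
        assert S(0.7 + 1e-9) == 0.0  # exp(-1) just after the knot, then forced to 0 beyond
        np.testing.assert_allclose(S.values, [np.exp(-1)])

    def test_matches_nelson_aalen_oracle(self, rng):
        # independent oracle: lifelines' Nelson-Aalen estimator of the
        # cumulative hazard of the residual sample, with g = 1
        from lifelines import NelsonAalenFitter

        eps = rng.normal(size=40)
        delta = rng.integers(0, 2, 40)
        delta[0] = 1
        res = ResidualSet(eps=eps, delta=delta, g=np.ones(40))
        S = estimate_error_survival(res)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(eps, event_observed=delta)
        expected = np.exp(-naf.cumulative_hazard_at_times(S.knots).to_numpy())
        np.testing.assert_allclose(S.values, expected, rtol=1e-10)

    def test_ties_aggregate_into_one_knot(self):
        eps = np.array([0.5, 0.5, 1.0])
        res = ResidualSet(eps=eps, delta=np.ones(3, dtype=int), g=np.ones(3))
        S = estimate_error_survival(res)
        np.testing.assert_allclose(S.knots, [0.5, 1.0])
        np.testing.assert_allclose(S.values, [np.exp(-2 / 3), np.exp(-2 / 3 - 1)])

    def test_zero_weight_subjects_drop_from_risk_sets(self):
        # a censored subject with g = 0 contributes nothing to denominators
        eps = np.array([0.0, 0.5, 1.0])
        delta = np.array([1, 0, 1])
        with_zero = estimate_error_survival(ResidualSet(eps, delta, g=np.array([1.0, 0.0, 1.0])))
        without = estimate_error_survival(
            ResidualSet(eps[[0, 2]], delta[[0, 2]], g=np.ones(2))
        )
        np.testing.assert_allclose(with_zero.values, without.values)

    def test_monotone_in_unit_interval(self, rng):
        eps = rng.normal(size=60)
        delta = rng.integers(0, 2, 60)
        delta[:5] = 1
        g = np.where(delta == 1, 1.0, rng.uniform(0, 1, 60))
        S = estimate_error_survival(ResidualSet(eps, delta, g))
        assert np.all(np.diff(S.values) <= 1e-12)
        assert S.values.min() >= 0 and S.values.max() <= 1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no observed events"):
            estimate_error_survival(
                ResidualSet(np.array([1.0]), np.array([0]), np.array([0.5]))
            )


class TestImputation:
    def test_uncensored_keep_log_time(self, rng):
        X = rng.normal(size=(6, 2))
        beta = np.array([0.3, 0.3])
        t = rng.uniform(0.5, 3.0, 6)
        ds = _dataset(t, np.ones(6), X)
        res = compute_residuals(beta, ds)
        res = ResidualSet(res.eps, res.delta, np.ones(6))
        S = estimate_error_survival(res)
        yhat = impute_log_response(beta, S, res, ds)
        np.testing.assert_allclose(yhat, np.log(t))

    def test_point_mass_expectation(self):
        # single knot with mass 1: censored subject below it gets beta'X + knot
        ds = _dataset([1.0, 2.0], [1, 0], np.array([[0.0], [1.0]]))
        beta = np.array([0.5])
        res = compute_residuals(beta, ds)
        res = ResidualSet(res.eps, res.delta, np.array([1.0, 0.5]))
        S = estimate_error_survival(res)
        assert len(S.knots) == 1
        yhat = impute_log_response(beta, S, res, ds)
        assert yhat[1] == pytest.approx(0.5 + S.knots[0])

    def test_matches_brute_force_discrete_expectation(self, rng):
        X = rng.normal(size=(30, 2))
        beta = np.array([0.6, -0.4])
        t = rng.uniform(0.2, 5.0, 30)
        delta = rng.integers(0, 2, 30)
        delta[:3] = 1
        ds = _dataset(t, delta, X)
        res = compute_residuals(beta, ds)
        g = np.where(delta == 1, 1.0, rng.uniform(0.2, 1.0, 30))
        res = ResidualSet(res.eps, res.delta, g)
        S = estimate_error_survival(res)
        yhat = impute_log_response(beta, S, res, ds)
        masses = S.masses()
        for i in np.where(delta == 0)[0]:
            sel = S.knots > res.eps[i]
            if masses[sel].sum() > 0:
                brute = float(np.sum(S.knots[sel] * masses[sel]) / np.sum(masses[sel]))
            else:
                brute = float(S.knots[-1])
            assert yhat[i] == pytest.approx(X[i] @ beta + brute)

    def test_censored_imputation_not_below_log_time(self, rng):
        X = rng.normal(size=(40, 2))
        beta = np.array([0.2, 0.7])
        t = rng.uniform(0.2, 5.0, 40)
        delta = rng.integers(0, 2, 40)
        delta[:4] = 1
        ds = _dataset(t, delta, X)
        res = compute_residuals(beta, ds)
        res = ResidualSet(res.eps, res.delta, np.where(delta == 1, 1.0, 0.6))
        S = estimate_error_survival(res)
        yhat = impute_log_response(beta, S, res, ds)
        cens = delta == 0
        assert np.all(yhat[cens] >= np.log(t[cens]) - 1e-10)

    def test_shift_equivariance(self, rng):
        # adding c to every log time shifts knots and imputations by c
        X = rng.normal(size=(25, 1))
        beta = np.array([0.4])
        t = rng.uniform(0.2, 4.0, 25)
        delta = rng.integers(0, 2, 25)
        delta[:2] = 1
        c = 0.8
        out = []
        for times in (t, t * np.exp(c)):
            ds = _dataset(times, delta, X)
            res = compute_residuals(beta, ds)
            res = ResidualSet(res.eps, res.delta, np.where(delta == 1, 1.0, 0.5))
            S = estimate_error_survival(res)
            out.append((S.knots.copy(), impute_log_response(beta, S, res, ds)))
        np.testing.assert_allclose(out[1][0], out[0][0] + c, rtol=1e-10)
        np.testing.assert_allclose(out[1][1], out[0][1] + c, rtol=1e-10)
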