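import numpy as np
import pytest

import mortrend as mt
from mortrend.fitting import initialize_parameters
from mortrend.models import ModelSpec, ParameterSet

from conftest import make_series


class TestDevianceAndResiduals:
    def test_perfect_fit_gives_zero(self):
        obs = np.array([0.01, 0.008, 0.006])
        dev, resid = mt.deviance_and_residuals(obs, obs, np.array([1e5, 1e5, 1e5]))
        assert dev == 0.0 and np.all(resid == 0.0)

    def test_hand_computed_single_year(self):
        # (0.011-0.010)/sqrt(0.01*0.99/1e6) = 10.0504
        dev, resid = mt.deviance_and_residuals(
            np.array([0.011]), np.array([0.010]), np.array([1e6]))
        assert resid[0] == pytest.approx(0.001 / np.sqrt(0.01 * 0.99 / 1e6), rel=1e-12)
        assert resid[0] == pytest.approx(10.05, abs=0.01)
        assert dev == pytest.approx(resid[0] ** 2)

    def test_degenerate_fitted_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            mt.deviance_and_residuals(np.array([0.5]), np.array([0.0]), np.array([10.0]))


class TestFitModel:
    def test_trend_only_nests_truth(self):
        # pure floored-logistic data, no bells: deviance collapses to ~0
        spec = ModelSpec(family="logistic")
        truth = ParameterSet(alpha=0.003, beta1=-1.5, beta2=-0.07)
        years = np.arange(1950, 2019)
        births = np.full(69, 1_000_000)
        rates = mt.eval_rate(years - 1930.0, truth, spec)
        s = make_series(years, births, np.round(rates * births).astype(int))
        fit = mt.fit_model(s, spec)
        assert fit.deviance < 1e-6 * fit.df or fit.deviance < 0.1
        assert fit.params.beta2 == pytest.approx(-0.07, rel=1e-4)

    def test_exact_recovery_two_term_toy(self):
        spec = ModelSpec(family="logistic", n_excess=2, width_ties={1: 0})
        truth = ParameterSet(alpha=0.003, beta1=-1.5, beta2=-0.07,
                             excess=[(5.0, 3.45, 0.13), (15.0, 3.85, 0.13)])
        years = np.arange(1950, 2019)
        births = np.full(69, 2_000_000)
        rates = mt.eval_rate(years - 1930.0, truth, spec)
        s = make_series(years, births, np.round(rates * births).astype(int))
        fit = mt.fit_model(s, spec)
        # bells are exchangeable; compare in time order
        est_sorted = sorted(fit.params.excess, key=lambda term: term.mu)
        for est, true in zip(est_sorted, truth.excess):
            assert est.amplitude == pytest.approx(true.amplitude, rel=1e-3)
            assert est.mu == pytest.approx(true.mu, rel=1e-3)
            assert est.sigma == pytest.approx(true.sigma, rel=1e-3)
        assert fit.params.beta2 == pytest.approx(truth.beta2, rel=1e-3)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=1e-3)
        assert fit.converged

    def test_df_counts_tied_width_once(self, eu5_fixture, eu5_ref):
        fit = mt.fit_model(eu5_fixture, eu5_ref.spec, init=eu5_ref.params)
        # 69 observations, 11 free parameters (tied width counted once)
        assert fit.df == 58
        assert fit.overdispersion == pytest.approx(fit.deviance / fit.df)

    def test_fixed_parameter_excluded_from_df(self, eu5_fixture, eu5_ref):
        fit = mt.fit_model(eu5_fixture, eu5_ref.spec, init=eu5_ref.params,
                           fixed={"beta2": eu5_ref.params.beta2}, compute_se=False)
        assert fit.df == 59 and "beta2" not in fit.free_names

    def test_identifiability_error_names_parameters(self):
        from mortrend.fitting import _check_identifiable

        # duplicated columns: perfectly collinear pair is named
        col = np.linspace(1.0, 2.0, 12)
        jac = np.column_stack([np.ones(12), col, col])
        with pytest.raises(mt.IdentifiabilityError, match="a1|mu1"):
            _check_identifiable(jac, ["beta1", "a1", "mu1"])
        # a parameter with no leverage at all (zero column) is also caught
        jac0 = np.column_stack([np.ones(12), np.zeros(12)])
        with pytest.raises(mt.IdentifiabilityError, match="a1"):
            _check_identifiable(jac0, ["beta1", "a1"])

    def test_standard_errors_scale_with_overdispersion(self, eu5_ref):
        cfg = mt.SimConfig(1950, 2018, eu5_ref.params, eu5_ref.spec,
                           births_per_year=1_000_000, seed=5)
        s = mt.simulate_series(cfg)
        plain = mt.fit_model(s, eu5_ref.spec, init=eu5_ref.params)
        scaled = mt.fit_model(s, eu5_ref.spec, init=eu5_ref.params, od_scaled_se=True)
        factor = np.sqrt(plain.overdispersion)
        assert scaled.se["beta2"] == pytest.approx(plain.se["beta2"] * factor, rel=1e-6)


class TestInitialization:
    def test_deterministic_across_calls(self, eu5_fixture, eu5_ref):
        a = initialize_parameters(eu5_fixture, eu5_ref.spec)
        b = initialize_parameters(eu5_fixture, eu5_ref.spec)
        assert np.array_equal(eu5_ref.spec.pack(a), eu5_ref.spec.pack(b))

    def test_trend_only_spec_skips_peak_stage(self, eu5_fixture):
        spec = ModelSpec(family="logistic")
        init = initialize_parameters(eu5_fixture, spec)
        assert init.excess == () and init.beta2 < 0

    def test_locates_reference_bells(self, eu5_fixture, eu5_ref):
        init = initialize_parameters(eu5_fixture, eu5_ref.spec)
        for seeded, true in zip(init.excess, eu5_ref.params.excess):
            assert seeded.mu == pytest.approx(true.mu, abs=0.2)


class TestLogLinearTrend:
    @staticmethod
    def _series_from_loglinear(a, b, years, births):
        t = years - 1930.0
        rates = np.exp(a + b * t)
        return make_series(years, births, np.round(rates * births).astype(int))

    def test_constant_rate_gives_zero_slope(self):
        years = np.arange(1950, 1990)
        s = self._series_from_loglinear(-4.0, 0.0, years, np.full(40, 10**6))
        fit = mt.fit_loglinear_trend(s, degree=1)
        assert fit.params.beta2 == pytest.approx(0.0, abs=1e-4)

    def test_recovers_exponential_decline(self):
        years = np.arange(1934, 1951)
        s = self._series_from_loglinear(-2.9, -0.045, years, np.full(17, 2_500_000))
        fit = mt.fit_loglinear_trend(s, degree=1)
        assert fit.params.beta1 == pytest.approx(-2.9, rel=1e-3)
        assert fit.params.beta2 == pytest.approx(-0.045, rel=1e-3)

    def test_window_exclusion_matches_fit_on_retained_years(self):
        years = np.arange(1934, 2019)
        rng = np.random.default_rng(11)
        t = years - 1930.0
        rates = np.exp(-2.8 - 0.03 * t + 1.2e-4 * t**2)
        births = np.full(years.size, 1_000_000)
        deaths = rng.poisson(births * rates)
        s = make_series(years, births, deaths)
        excl = mt.fit_loglinear_trend(s, degree=2, exclude_window=(1950, 2000))
        retained = mt.exclude_years(s, range(1950, 2001))
        direct = mt.fit_loglinear_trend(retained, degree=2)
        assert excl.params.beta2 == pytest.approx(direct.params.beta2, rel=1e-10)
        # predictions cover the excluded window for excess estimation
        est = mt.excess_summary(s, excl, excl.spec, window=(1950, 2000))
        assert est.observed == s.deaths[(s.year >= 1950) & (s.year <= 2000)].sum()

    def test_too_few_observations_rejected(self):
        s = make_series([1950, 1951, 1952], [1000] * 3, [10, 9, 8])
        with pytest.raises(ValueError, match="retained"):
            mt.fit_loglinear_trend(s, degree=3, exclude_window=(1952, 1952))


class TestOracleEquivalence:
    def test_matches_brute_force_on_small_toy(self):
        """The reweighted optimum minimises its own final weighted objective.

        An independent seeded global optimiser (differential evolution with
        polish) attacks the same frozen-weight objective on an 8-point,
        one-bell toy; the two objective values must agree to 1e-6 relative.
        """
        from scipy.optimize import differential_evolution

        spec = ModelSpec(family="logistic", n_excess=1)
        truth = ParameterSet(alpha=0.004, beta1=-2.0, beta2=-0.06,
                             excess=[(6.0, 3.0, 0.15)])
        years = np.arange(1946, 1954)
        births = np.full(8, 500_000)
        rng = np.random.default_rng(3)
        rates = mt.eval_rate(years - 1930.0, truth, spec)
        s = make_series(years, births, rng.binomial(births, rates))

        fit = mt.fit_model(s, spec, init=truth)
        w2 = 1.0 / fit.var  # final weights, frozen

        def objective(x):
            try:
                r = mt.eval_rate(s.t.astype(float), spec.unpack(x), spec)
            except ValueError:
                return 1e12
            if np.any(r <= 0) or np.any(r >= 1):
                return 1e12
            return float(np.sum(w2 * (s.rate - r) ** 2))

        bounds = [(0, 0.008), (-4, 0), (-0.2, 0.05), (0, 20), (2.0, 3.5), (0.01, 0.6)]
        res = differential_evolution(objective, bounds, seed=12345, tol=1e-12,
                                     maxiter=400, polish=True)
        q_fit = objective(spec.pack(fit.params))
        q_oracle = res.fun
        assert q_fit <= q_oracle * (1 + 1e-6)
        assert abs(q_fit - q_oracle) <= 1e-6 * max(q_fit, q_oracle)
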