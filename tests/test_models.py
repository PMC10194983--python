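import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import mortrend as mt
from mortrend.models import ExcessTerm, ModelSpec, ParameterSet


class TestExcessTerm:
    def test_zero_amplitude_is_zero_everywhere(self):
        t = np.arange(1, 101, dtype=float)
        assert np.all(mt.excess_term(t, 0.0, 3.0, 0.2) == 0.0)

    def test_centre_value_is_amplitude_over_t(self):
        # Gaussian factor is 1 at log t == mu
        assert mt.excess_term(20.0, 1.0, np.log(20.0), 0.1) == pytest.approx(1 / 20)

    def test_rejects_time_below_one(self):
        with pytest.raises(ValueError, match=">= 1"):
            mt.excess_term(0.5, 1.0, 3.0, 0.1)

    def test_numeric_argmax_matches_lognormal_mode(self):
        # dense-grid argmax vs exp(mu - sigma^2), pooled-Europe first bell
        a, mu, sigma = 4.582, 3.473, 0.133
        t = np.linspace(1, 100, 400_000)
        vals = mt.excess_term(t, a, mu, sigma)
        t_star = t[np.argmax(vals)]
        assert t_star == pytest.approx(np.exp(mu - sigma**2), abs=5e-3)
        assert t_star + 1930 == pytest.approx(1961.7, abs=0.1)

    @given(st.floats(2.5, 4.2), st.floats(0.03, 0.5))
    @settings(max_examples=25, deadline=None)
    def test_mode_formula_property(self, mu, sigma):
        t = np.linspace(1, 120, 200_000)
        t_star = t[np.argmax(mt.excess_term(t, 1.0, mu, sigma))]
        assert abs(t_star - np.exp(mu - sigma**2)) < 0.05


class TestLinearPredictor:
    def test_all_zero_coefficients(self):
        spec = ModelSpec(family="expcubic")
        params = ParameterSet(beta1=0.0, beta2=0.0)
        assert mt.linear_predictor(np.array([5.0]), params, spec)[0] == 0.0

    def test_cubic_transcription(self):
        # direct polynomial evaluation at the US exponential-cubic estimates
        spec = ModelSpec(family="expcubic")
        params = ParameterSet(beta1=-2.729, beta2=-0.043, beta3=9.8e-05, beta4=9.0e-07)
        expected = -2.729 + -0.043 * 10 + 9.8e-05 * 100 + 9.0e-07 * 1000
        assert mt.linear_predictor(10.0, params, spec)[()] == pytest.approx(expected, rel=1e-12)

    def test_tied_width_follows_master(self):
        spec = ModelSpec(family="logistic", n_excess=2, width_ties={1: 0})
        x = spec.pack(ParameterSet(alpha=0.003, beta1=-1.5, beta2=-0.07,
                                   excess=[(5, 3.4, 0.2), (7, 3.9, 0.2)]))
        # one width parameter only; changing it moves both terms
        names = spec.free_parameter_names()
        assert names.count("sigma1") == 1 and "sigma2" not in names
        x[names.index("sigma1")] = 0.11
        p = spec.unpack(x)
        assert p.excess[0].sigma == p.excess[1].sigma == 0.11


class TestEvalRate:
    def test_logistic_floor_is_lower_limit(self):
        spec = ModelSpec(family="logistic")
        params = ParameterSet(alpha=0.0048, beta1=-2.7, beta2=-0.05)
        rate = mt.eval_rate(np.array([500.0]), params, spec)
        assert rate[0] == pytest.approx(0.0048, rel=1e-6)

    @pytest.mark.parametrize("family", ["logistic", "expcubic"])
    def test_monotone_decline_without_excess(self, family):
        if family == "logistic":
            params = ParameterSet(alpha=0.002, beta1=-1.5, beta2=-0.07)
        else:
            params = ParameterSet(beta1=-3.0, beta2=-0.04)
        spec = ModelSpec(family=family)
        r = mt.eval_rate(np.arange(1.0, 90.0), params, spec)
        assert np.all(np.diff(r) < 0)

    @given(st.floats(-700, 700))
    @settings(max_examples=60, deadline=None)
    def test_stable_logistic_identity(self, eta):
        # alpha + (1-alpha)/(1 + 1/exp(eta)) computed stably for any finite eta
        alpha = 0.0048
        stable = alpha + (1 - alpha) * expit(eta)
        if abs(eta) < 500:
            naive = alpha + (1 - alpha) / (1 + 1 / np.exp(eta))
            assert stable == pytest.approx(naive, rel=1e-12, abs=1e-300)
        assert np.isfinite(stable) and alpha <= stable <= 1.0

    def test_nan_parameters_rejected(self):
        spec = ModelSpec(family="expcubic")
        with pytest.raises(ValueError, match="NaN"):
            mt.eval_rate(np.array([5.0]), ParameterSet(beta1=np.nan, beta2=0.0), spec)

    def test_continuity_in_parameters(self, eu5_ref):
        t = np.arange(20.0, 89.0)
        x = eu5_ref.spec.pack(eu5_ref.params)
        base = mt.eval_rate(t, eu5_ref.params, eu5_ref.spec)
        for i in range(x.size):
            xp = x.copy()
            xp[i] += 1e-7 * max(1.0, abs(x[i]))
            shifted = mt.eval_rate(t, eu5_ref.spec.unpack(xp), eu5_ref.spec)
            assert np.max(np.abs(shifted - base)) < 1e-4


class TestUndisturbed:
    def test_identity_without_excess_terms(self):
        spec = ModelSpec(family="logistic")
        params = ParameterSet(alpha=0.002, beta1=-1.5, beta2=-0.07)
        t = np.arange(20.0, 71.0)
        assert np.array_equal(mt.undisturbed_rate(t, params, spec),
                              mt.eval_rate(t, params, spec))

    def test_excess_is_nonnegative_at_reference(self, eu5_ref):
        t = np.arange(20.0, 71.0)  # 1950-2000
        diff = (mt.eval_rate(t, eu5_ref.params, eu5_ref.spec)
                - mt.undisturbed_rate(t, eu5_ref.params, eu5_ref.spec))
        assert np.all(diff >= 0)

    def test_difference_curve_peaks_at_mode_formula(self):
        # well-separated mild bells on a gentle trend: each local max of the
        # rate-scale difference curve sits at exp(mu - sigma^2); the formula
        # is exact on the predictor scale, so the rate-scale agreement needs
        # the small-perturbation regime
        spec = ModelSpec(family="logistic", n_excess=2)
        params = ParameterSet(alpha=0.002, beta1=-1.5, beta2=-0.008,
                              excess=[(1.0, 3.0, 0.05), (1.5, 3.8, 0.05)])
        t = np.linspace(10, 80, 70_001)
        diff = mt.eval_rate(t, params, spec) - mt.undisturbed_rate(t, params, spec)
        eta = mt.linear_predictor(t, params, spec) - mt.linear_predictor(
            t, params.zero_excess(), spec)
        for term in params.excess:
            mode = np.exp(term.mu - term.sigma**2)
            window = (t > mode - 5) & (t < mode + 5)
            # exact on the predictor scale
            assert t[window][np.argmax(eta[window])] == pytest.approx(mode, abs=0.01)
            # close on the rate scale
            assert t[window][np.argmax(diff[window])] == pytest.approx(mode, abs=0.1)

    def test_war_term_kept_in_baseline_by_default(self):
        spec = ModelSpec(family="expcubic", n_excess=2, war_term=True)
        params = ParameterSet(beta1=-3.0, beta2=-0.03,
                              excess=[(6.0, 2.6, 0.15), (8.0, 3.8, 0.12)])
        t = np.arange(5.0, 90.0)
        base = mt.undisturbed_rate(t, params, spec)
        trend = mt.undisturbed_rate(t, params, spec, zero_war_term=True)
        assert np.any(base > trend)  # wartime bell still in the baseline
        assert np.array_equal(trend, mt.eval_rate(t, params.zero_excess(), spec))


class TestSpecValidation:
    def test_pack_unpack_round_trip(self, eu5_ref):
        x = eu5_ref.spec.pack(eu5_ref.params)
        assert np.array_equal(eu5_ref.spec.pack(eu5_ref.spec.unpack(x)), x)

    def test_tie_must_point_backwards(self):
        with pytest.raises(ValueError, match="tie"):
            ModelSpec(family="logistic", n_excess=2, width_ties={0: 1})

    def test_family_alias_resolution(self):
        assert ModelSpec(family="model1").family == "logistic"
        spec3 = ModelSpec(family="model3", n_excess=2)
        assert spec3.family == "expcubic" and spec3.war_term

    def test_mismatched_term_count_rejected(self):
        spec = ModelSpec(family="logistic", n_excess=2)
        with pytest.raises(ValueError, match="excess"):
            spec.pack(ParameterSet(alpha=0.01, beta1=-2, beta2=-0.05))

    def test_intervention_design_vectors(self):
        years = np.arange(1990, 1998)
        pulse = mt.Intervention("pulse", 1994).design(years)
        step = mt.Intervention("step", 1995).design(years)
        assert pulse.tolist() == [0, 0, 0, 0, 1, 0, 0, 0]
        assert step.tolist() == [0, 0, 0, 0, 0, 1, 1, 1]
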