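import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_series
from splitbelt import (
    FitConfig,
    SimulationSpec,
    ThetaSingle,
    aic,
    ci_linearized,
    ci_profile,
    compare_intervals,
    fit,
    jacobian,
    select_model,
    simulate_series,
)
from splitbelt.inference import IntervalEstimate, profile_interval, t_intervals

LN2 = math.log(2.0)


def _fit_result_stub(model_kind, sse, n):
    """Minimal stand-in carrying just what aic() consumes."""

    class Stub:
        pass

    stub = Stub()
    stub.model_kind = model_kind
    stub.sse = sse
    stub.n_strides = n
    return stub


class TestAIC:
    def test_formula_at_unit_sse(self):
        assert aic(_fit_result_stub("single", 1.0, 100)) == pytest.approx(8.0)

    def test_parameter_counts_include_residual_variance(self):
        # same SSE and N: the double model pays 2 * (6 - 4) = 4 more
        a_single = aic(_fit_result_stub("single", 0.5, 200))
        a_double = aic(_fit_result_stub("double", 0.5, 200))
        assert a_double - a_single == pytest.approx(4.0)

    def test_monotone_in_sse(self):
        assert aic(_fit_result_stub("single", 0.2, 100)) < aic(
            _fit_result_stub("single", 0.3, 100)
        )

    def test_zero_sse_rejected(self):
        with pytest.raises(ValueError):
            aic(_fit_result_stub("single", 0.0, 100))


class TestSelectModel:
    @pytest.mark.parametrize(
        "sse_double_log_gap, expected",
        [(-3.0, "double"), (-2.0, "single"), (5.0, "single")],
    )
    def test_delta_rule_with_strict_inequality(self, sse_double_log_gap, expected):
        # craft SSEs so that delta = 2*(6-4) + N*(lnSSE_d - lnSSE_s) hits the
        # requested value exactly
        n = 100
        sse_s = 1.0
        target_delta = sse_double_log_gap
        sse_d = math.exp((target_delta - 4.0) / n)
        result = select_model(
            _fit_result_stub("single", sse_s, n),
            _fit_result_stub("double", sse_d, n),
        )
        assert result.delta == pytest.approx(target_delta, abs=1e-9)
        assert result.selected == expected

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            select_model(
                _fit_result_stub("single", 1.0, 100),
                _fit_result_stub("double", 1.0, 101),
            )


class TestJacobian:
    def test_single_rows(self):
        J = jacobian(ThetaSingle(a=1.0, b=0.0, c=0.0), 1)
        np.testing.assert_allclose(J, [[1.0, 1.0, 1.0]])
        J2 = jacobian(ThetaSingle(a=2.0, b=-LN2, c=0.0), 1)
        np.testing.assert_allclose(J2, [[0.5, 1.0, 1.0]])

    @pytest.mark.parametrize(
        "theta",
        [
            ThetaSingle(a=0.1, b=-0.02, c=0.02),
            ThetaSingle(a=-0.3, b=-0.3, c=0.1),
        ],
    )
    def test_matches_finite_differences(self, theta):
        from splitbelt import eval_single

        n = 30
        J = jacobian(theta, n)
        eps = 1e-7
        base = theta.to_array()
        for j in range(3):
            up, down = base.copy(), base.copy()
            up[j] += eps
            down[j] -= eps
            fd = (
                eval_single(ThetaSingle.from_array(up), n)
                - eval_single(ThetaSingle.from_array(down), n)
            ) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-6)

    def test_double_matches_finite_differences(self):
        from splitbelt import ThetaDouble, eval_double

        theta = ThetaDouble(as_=-0.1, bs=-0.003, af=-0.04, bf=-0.03, c=0.02)
        n = 30
        J = jacobian(theta, n)
        eps = 1e-7
        base = theta.to_array()
        for j in range(5):
            up, down = base.copy(), base.copy()
            up[j] += eps
            down[j] -= eps
            fd = (
                eval_double(ThetaDouble.from_array(up), n)
                - eval_double(ThetaDouble.from_array(down), n)
            ) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-6)


class TestLinearizedIntervals:
    def test_pure_mean_model_reduces_to_t_interval(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.1, 0.05, 40)
        sse = float(np.sum((y - y.mean()) ** 2))
        (interval,) = t_intervals(
            np.ones((40, 1)), sse, np.array([y.mean()]), alpha=0.05
        )
        s = math.sqrt(sse / 39)
        expected_half = stats.t.ppf(0.975, 39) * s / math.sqrt(40)
        assert interval.upper - interval.estimate == pytest.approx(expected_half)

    def test_noise_free_fit_gives_vanishing_width(self):
        truth = ThetaSingle(a=0.1, b=-0.05, c=0.02)
        series = simulate_series(
            SimulationSpec(theta=truth, sigma=0.0, n_strides=200)
        )
        result = fit(series, "single", FitConfig(seed=1))
        for interval in ci_linearized(result).values():
            assert interval.width is not None
            assert interval.width < 1e-4

    def test_width_scales_inverse_sqrt_n(self):
        truth = ThetaSingle(a=0.1, b=-0.02, c=0.02)
        widths = {}
        for n in (400, 1600):
            spec = SimulationSpec(theta=truth, sigma=0.006, n_strides=n)
            ratio = []
            for seed in range(8):
                series = simulate_series(spec, seed=seed)
                result = fit(series, "single", FitConfig(seed=seed))
                ratio.append(ci_linearized(result)["c"].width)
            widths[n] = np.mean(ratio)
        # quadrupling N should roughly halve the width of the c interval
        assert widths[400] / widths[1600] == pytest.approx(2.0, rel=0.35)


class TestProfileIntervals:
    def test_pure_mean_closed_form(self):
        y = np.array([-1.0, 0.0, 1.0])

        def profile_sse(c):
            return float(np.sum((y - c) ** 2))

        interval = profile_interval(
            profile_sse, 0.0, 2.0, n_obs=3, p=1,
            bracket_lower=-10.0, bracket_upper=10.0,
        )
        expected = stats.t.ppf(0.975, 2) / math.sqrt(3)
        assert interval.lower == pytest.approx(-expected, abs=1e-6)
        assert interval.upper == pytest.approx(expected, abs=1e-6)

    def test_contains_estimate(self, noisy_single_series, fast_config):
        result = fit(noisy_single_series, "single", fast_config)
        for j in range(3):
            interval = ci_profile(result, noisy_single_series, j)
            assert interval.lower <= interval.estimate <= interval.upper

    def test_agrees_with_linearized_on_near_linear_data(self):
        truth = ThetaSingle(a=0.1, b=-0.02, c=0.02)
        series = simulate_series(
            SimulationSpec(theta=truth, sigma=0.002, n_strides=900), seed=6
        )
        result = fit(series, "single", FitConfig(seed=6))
        lin = ci_linearized(result)["c"]
        prof = ci_profile(result, series, 2)
        assert abs(prof.lower - lin.lower) < 0.1 * lin.width
        assert abs(prof.upper - lin.upper) < 0.1 * lin.width

    def test_linear_in_all_parameters_matches_t_interval(self):
        # a model linear in its only parameter: profile and linearized
        # intervals coincide through the F(1, nu) = t(nu)^2 identity
        rng = np.random.default_rng(9)
        y = rng.normal(0.05, 0.01, 25)

        def profile_sse(c):
            return float(np.sum((y - c) ** 2))

        c_hat = float(y.mean())
        sse = profile_sse(c_hat)
        prof = profile_interval(
            profile_sse, c_hat, sse, n_obs=25, p=1,
            bracket_lower=-1.0, bracket_upper=1.0,
        )
        (lin,) = t_intervals(np.ones((25, 1)), sse, np.array([c_hat]))
        assert prof.lower == pytest.approx(lin.lower, abs=1e-6)
        assert prof.upper == pytest.approx(lin.upper, abs=1e-6)

    def test_no_root_in_extended_range_is_undefined(self):
        # a profile that never climbs: SSE flat in the parameter
        interval = profile_interval(
            lambda v: 2.0, 0.0, 2.0, n_obs=10, p=1,
            bracket_lower=-1.0, bracket_upper=1.0,
        )
        assert interval.lower is None and interval.upper is None
        assert "no sign change" in interval.note


class TestCompareIntervals:
    def _iv(self, lo, hi, est=None):
        if est is None:
            est = 0.5 * ((lo if lo is not None else hi) + (hi if hi is not None else lo))
        return IntervalEstimate(estimate=est, lower=lo, upper=hi)

    def test_disjoint_is_significant(self):
        res = compare_intervals(self._iv(0.0, 1.0), self._iv(2.0, 3.0))
        assert res.overlap == "no" and res.significant

    def test_overlap_is_not_significant(self):
        res = compare_intervals(self._iv(0.0, 2.0), self._iv(1.0, 3.0))
        assert res.overlap == "yes" and not res.significant

    def test_undefined_endpoints_mean_indeterminate_overlap(self):
        res = compare_intervals(
            self._iv(0.030, None, est=0.034), self._iv(None, None, est=0.0)
        )
        assert res.overlap == "yes" and not res.significant
        assert "indeterminate" in res.verdict
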