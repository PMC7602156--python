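import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_overshoot, sample_admissible_overshoot_theta
from splitbelt import (
    ThetaDouble,
    ThetaSingle,
    eval_double,
    eval_single,
    half_change_strides,
    overshoot,
    overshoot_map,
    to_common_language,
)
from splitbelt.models import OvershootGrid

LN2 = math.log(2.0)


class TestEvaluation:
    @pytest.mark.parametrize(
        "theta, n, expected",
        [
            (ThetaSingle(a=0.0, b=-0.1, c=0.3), 4, [0.3] * 4),
            (ThetaSingle(a=1.0, b=0.0, c=0.0), 3, [1.0] * 3),
            (ThetaSingle(a=1.0, b=-LN2, c=0.0), 1, [0.5]),
        ],
    )
    def test_single_examples(self, theta, n, expected):
        np.testing.assert_allclose(eval_single(theta, n), expected, atol=1e-15)

    def test_double_all_zero_amplitudes(self):
        theta = ThetaDouble(as_=0.0, bs=-0.1, af=0.0, bf=-0.2, c=0.0)
        np.testing.assert_array_equal(eval_double(theta, 5), np.zeros(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-2, 2),
        st.floats(-LN2, 0),
        st.floats(-1, 1),
        st.floats(-LN2, 0),
    )
    def test_double_with_zero_fast_amplitude_degenerates_to_single(
        self, a, bs, c, bf
    ):
        double = ThetaDouble(as_=a, bs=bs, af=0.0, bf=bf, c=c)
        single = ThetaSingle(a=a, b=bs, c=c)
        np.testing.assert_array_equal(
            eval_double(double, 20), eval_single(single, 20)
        )


class TestOvershoot:
    def test_same_sign_amplitudes_undefined(self):
        theta = ThetaDouble(as_=0.3, bs=-0.01, af=0.2, bf=-0.1, c=0.0)
        assert not overshoot(theta).defined

    def test_reference_point(self):
        theta = ThetaDouble(as_=0.5, bs=-0.01, af=-0.5, bf=-0.1, c=0.0)
        res = overshoot(theta)
        assert res.defined
        assert res.ncrit == pytest.approx(25.584, abs=5e-4)
        assert res.ycrit == pytest.approx(0.3484, abs=5e-5)

    def test_sign_flip_mirrors_overshoot(self):
        up = overshoot(ThetaDouble(as_=0.5, bs=-0.01, af=-0.5, bf=-0.1, c=0.0))
        down = overshoot(ThetaDouble(as_=-0.5, bs=-0.01, af=0.5, bf=-0.1, c=0.0))
        assert down.ycrit == pytest.approx(-up.ycrit, abs=1e-12)
        assert down.ncrit == pytest.approx(up.ncrit, abs=1e-12)

    def test_equal_rates_reported_undefined_with_note(self):
        res = overshoot(ThetaDouble(as_=0.5, bs=-0.1, af=-0.5, bf=-0.1, c=0.0))
        assert not res.defined and "denominator" in res.note

    def test_matches_brute_force_extremisation(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            as_, bs, af, bf, c = sample_admissible_overshoot_theta(rng)
            res = overshoot(ThetaDouble(as_=as_, bs=bs, af=af, bf=bf, c=c))
            assert res.defined
            oracle = brute_force_overshoot(as_, bs, af, bf, c)
            assert oracle is not None
            assert res.ycrit == pytest.approx(oracle[1], abs=1e-9)

    def test_in_range_flag(self):
        theta = ThetaDouble(as_=0.5, bs=-0.01, af=-0.5, bf=-0.1, c=0.0)
        assert overshoot(theta, n_strides=100).in_range is True
        assert overshoot(theta, n_strides=10).in_range is False


class TestHalfChange:
    @pytest.mark.parametrize(
        "rate, expected", [(-LN2, 1), (-0.01, 69), (-LN2 / 3.5, 3)]
    )
    def test_floor_of_half_life(self, rate, expected):
        assert half_change_strides(rate) == expected

    def test_nonnegative_rate_rejected(self):
        with pytest.raises(ValueError):
            half_change_strides(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-2.0, -1e-4), st.floats(1e-4, 1.0))
    def test_monotone_nonincreasing_in_rate_magnitude(self, rate, extra):
        faster = rate - extra
        assert half_change_strides(faster) <= half_change_strides(rate)


class TestCommonLanguage:
    def test_single_transform(self):
        cl = to_common_language(ThetaSingle(a=0.1, b=-LN2, c=0.02), 0.005)
        assert cl.initial_asymmetry == pytest.approx(0.12)
        assert cl.total_change == pytest.approx(0.1)
        assert cl.half_change == (1,)
        assert cl.final_asymmetry == pytest.approx(0.02)
        assert not cl.overshoot.defined
        assert cl.residual_sd == 0.005

    def test_double_zero_amplitudes_flat_and_degenerate(self):
        theta = ThetaDouble(as_=0.0, bs=-0.1, af=0.0, bf=-0.2, c=0.05)
        cl = to_common_language(theta, 0.006)
        assert cl.initial_asymmetry == cl.final_asymmetry == 0.05
        assert cl.total_change == 0.0
        assert not cl.overshoot.defined
        assert cl.degenerate

    def test_double_opposite_signs_carries_overshoot(self):
        theta = ThetaDouble(as_=0.5, bs=-0.01, af=-0.5, bf=-0.1, c=0.0)
        cl = to_common_language(theta, 0.006, n_strides=750)
        assert cl.overshoot.defined
        assert cl.overshoot.ycrit == pytest.approx(0.3484, abs=5e-5)

    def test_json_uses_ud_for_undefined_overshoot(self):
        cl = to_common_language(ThetaSingle(a=0.1, b=-0.1, c=0.0), 0.005)
        assert cl.to_json()["overshoot"]["ycrit"] == "UD"


class TestOvershootMap:
    def test_same_sign_restriction_all_undefined(self):
        grid = OvershootGrid(
            as_values=np.array([0.2, 0.5]),
            af_values=np.array([0.3, 0.8]),
        )
        table = overshoot_map(grid)
        assert len(table) > 0 and not table["defined"].any()

    def test_default_grid_overshoots_span_unit_range(self):
        # overshoots whose critical stride is observable (ncrit >= 0) stay
        # inside [-1, 1], and the grid can realise nearly any value in it
        table = overshoot_map()
        observable = table[table["defined"] & (table["ncrit"] >= 0)]
        assert len(observable) > 0
        assert observable["ycrit"].abs().le(1.0 + 1e-9).all()
        assert observable["ycrit"].max() > 0.95
        assert observable["ycrit"].min() < -0.95

    def test_reference_grid_point(self):
        table = overshoot_map(
            OvershootGrid(
                as_values=np.array([0.5]),
                af_values=np.array([-0.5]),
                bs_values=np.array([-0.01]),
                bf_values=np.array([-0.1]),
            )
        )
        assert len(table) == 1
        assert table["ycrit"].iloc[0] == pytest.approx(0.3484, abs=5e-5)

    def test_empty_admissible_grid_rejected(self):
        with pytest.raises(ValueError):
            overshoot_map(
                OvershootGrid(
                    bs_values=np.array([-0.5]), bf_values=np.array([-0.1])
                )
            )
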