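"""Unit tests for the RTD mathematics: densities, moments, convolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rtdkit as rk
from rtdkit.core import TOL_NUMERIC
from rtdkit.errors import ContractError, InvalidInputError, RangeError


class TestNormalizeToE:
    def test_rectangular_pulse_becomes_flat_unit_density(self):
        grid = rk.TimeGrid(0.0, 0.5, 11)
        trace = rk.ConcentrationTrace(grid, np.full(11, 2.0))
        e = rk.normalize_to_E(trace)
        assert np.allclose(e.density, 0.2)
        assert e.integral() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_already_normalized_curve(self):
        grid = rk.TimeGrid(0.0, 1.0, 600)
        e = rk.e_cstr(50.0, grid)
        again = rk.normalize_to_E(rk.ConcentrationTrace(grid, e.density))
        assert np.allclose(again.density, e.density)

    def test_triangle_peak_scales_by_brute_force_integral(self):
        # triangle peaking at 4 at t=10 over [0, 20]: integral is 40
        grid = rk.TimeGrid(0.0, 0.5, 41)
        t = grid.times
        c = np.where(t <= 10, 0.4 * t, 0.4 * (20 - t))
        integral = np.trapezoid(c, dx=0.5)
        assert integral == pytest.approx(40.0)
        e = rk.normalize_to_E(rk.ConcentrationTrace(grid, c))
        assert e.density[20] == pytest.approx(0.1)

    def test_all_zero_trace_rejected(self):
        grid = rk.TimeGrid(0.0, 1.0, 10)
        trace = rk.ConcentrationTrace(grid, np.zeros(10))
        with pytest.raises(InvalidInputError, match="integrates"):
            rk.normalize_to_E(trace)

    def test_baseline_subtraction_from_prepulse_window(self):
        grid = rk.TimeGrid(0.0, 1.0, 400)
        e = rk.e_unit(rk.RTDParams(tau_tank=30.0, theta=50.0), grid)
        trace = rk.ConcentrationTrace(grid, 100.0 + 50.0 * e.density * 100)
        recovered = rk.normalize_to_E(trace, baseline_window=20)
        assert np.allclose(recovered.density, e.density, atol=1e-4)


class TestMRT:
    def test_flat_density_has_midpoint_mean(self):
        grid = rk.TimeGrid(0.0, 0.5, 11)
        e = rk.EtCurve(grid, np.full(11, 0.2))
        assert rk.mrt_of_curve(e) == pytest.approx(2.5, abs=1e-9)

    def test_unit_model_mean_is_delay_plus_two_tanks(self):
        params = rk.RTDParams(tau_tank=5.0, theta=10.0)
        grid = rk.default_grid(10.0, 5.0, step=0.05)
        assert rk.mrt_of_curve(rk.e_unit(params, grid)) == pytest.approx(20.0, abs=0.1)

    def test_erlang2_mean_is_twice_tau(self):
        params = rk.RTDParams(tau_tank=104.5, theta=0.0)
        grid = rk.TimeGrid(0.0, 0.1, 20001)
        assert rk.mrt_of_curve(rk.e_unit(params, grid)) == pytest.approx(209.0, abs=0.2)

    def test_unnormalized_curve_rejected(self):
        grid = rk.TimeGrid(0.0, 1.0, 10)
        e = rk.EtCurve(grid, np.full(10, 1.0))
        with pytest.raises(ContractError, match="not normalized"):
            rk.mrt_of_curve(e)


class TestPfr:
    def test_zero_delay_puts_all_mass_at_first_node(self):
        grid = rk.TimeGrid(0.0, 1.0, 10)
        e = rk.e_pfr(0.0, grid)
        assert np.all(e.density[1:] == 0)
        assert e.integral() == pytest.approx(1.0)

    def test_on_node_delay_is_single_node_mass(self):
        grid = rk.TimeGrid(0.0, 1.0, 10)
        e = rk.e_pfr(4.0, grid)
        assert e.density[4] == pytest.approx(1.0)
        assert np.count_nonzero(e.density) == 1

    @pytest.mark.parametrize("theta", [2.5, 3.75, 0.5])
    def test_between_node_delay_preserves_discrete_mean(self, theta):
        grid = rk.TimeGrid(0.0, 1.0, 12)
        e = rk.e_pfr(theta, grid)
        assert e.integral() == pytest.approx(1.0, abs=1e-12)
        assert rk.mrt_of_curve(e) == pytest.approx(theta, abs=1e-12)

    def test_delay_beyond_grid_rejected(self):
        with pytest.raises(RangeError, match="beyond"):
            rk.e_pfr(100.0, rk.TimeGrid(0.0, 1.0, 50))


class TestCstr:
    def test_density_at_origin_is_inverse_tau(self):
        grid = rk.TimeGrid(0.0, 1.0, 2000)
        e = rk.e_cstr(100.0, grid)
        assert e.density[0] == pytest.approx(0.01, rel=1e-3)

    def test_mean_equals_tau(self):
        grid = rk.TimeGrid(0.0, 0.5, 1201)  # spans 12 tau
        assert rk.mrt_of_curve(rk.e_cstr(50.0, grid)) == pytest.approx(50.0, abs=0.1)

    def test_fine_grid_first_moment(self):
        grid = rk.TimeGrid(0.0, 0.001, 20001)
        e = rk.e_cstr(1.0, grid)
        assert np.trapezoid(grid.times * e.density, dx=0.001) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            rk.e_cstr(0.0, rk.TimeGrid(0.0, 1.0, 10))


class TestConvolution:
    def test_delta_at_zero_is_identity_element(self):
        grid = rk.TimeGrid(0.0, 1.0, 800)
        e = rk.e_unit(rk.RTDParams(tau_tank=40.0, theta=30.0), grid)
        conv = rk.convolve_rtd(e, rk.e_pfr(0.0, grid))
        assert np.allclose(conv.density, e.density, atol=1e-9)

    def test_two_equal_tanks_give_erlang2(self):
        grid = rk.TimeGrid(0.0, 0.1, 8000)
        tau = 50.0
        conv = rk.convolve_rtd(rk.e_cstr(tau, grid), rk.e_cstr(tau, grid))
        erlang = rk.e_unit(rk.RTDParams(tau_tank=tau, theta=0.0), grid)
        assert np.max(np.abs(conv.density - erlang.density)) < 1e-3
        mode_t = grid.times[np.argmax(conv.density)]
        assert mode_t == pytest.approx(tau, abs=0.2)

    def test_mrt_additivity(self):
        grid = rk.TimeGrid(0.0, 0.1, 15000)
        conv = rk.convolve_rtd(rk.e_cstr(30.0, grid), rk.e_cstr(70.0, grid))
        assert rk.mrt_of_curve(conv) == pytest.approx(100.0, abs=0.2)

    def test_mismatched_grids_rejected(self):
        e1 = rk.e_cstr(10.0, rk.TimeGrid(0.0, 1.0, 200))
        e2 = rk.e_cstr(10.0, rk.TimeGrid(0.0, 0.5, 200))
        with pytest.raises(ContractError):
            rk.convolve_rtd(e1, e2)

    def test_associativity(self):
        grid = rk.TimeGrid(0.0, 1.0, 1200)
        e1 = rk.e_cstr(20.0, grid)
        e2 = rk.e_unit(rk.RTDParams(tau_tank=30.0, theta=40.0), grid)
        e3 = rk.e_cstr(15.0, grid)
        left = rk.convolve_rtd(rk.convolve_rtd(e1, e2), e3)
        right = rk.convolve_rtd(e1, rk.convolve_rtd(e2, e3))
        assert np.max(np.abs(left.density - right.density)) < 1e-6


class TestUnitModel:
    def test_zero_before_delay(self):
        grid = rk.TimeGrid(0.0, 1.0, 500)
        e = rk.e_unit(rk.RTDParams(tau_tank=20.0, theta=100.0), grid)
        assert np.all(e.density[grid.times < 100.0] == 0)

    def test_mode_at_delay_plus_tau(self):
        grid = rk.TimeGrid(0.0, 0.01, 20000)
        e = rk.e_unit(rk.RTDParams(tau_tank=5.0, theta=10.0), grid)
        assert grid.times[np.argmax(e.density)] == pytest.approx(15.0, abs=0.02)

    def test_feed_frame_regime_mean(self):
        params = rk.RTDParams(tau_tank=64.0, theta=164.5)
        grid = rk.default_grid(164.5, 64.0, step=0.25)
        assert rk.mrt_of_curve(rk.e_unit(params, grid)) == pytest.approx(292.5, abs=0.3)


class TestGeneralTwoTank:
    def test_zero_before_delay(self):
        grid = rk.TimeGrid(0.0, 1.0, 800)
        e = rk.e_unit_general(rk.GeneralTwoTankParams(40.0, 20.0, theta=50.0), grid)
        assert np.all(e.density[grid.times < 50.0] == 0)

    def test_mean_is_delay_plus_both_tanks(self):
        grid = rk.TimeGrid(0.0, 0.1, 15000)
        e = rk.e_unit_general(rk.GeneralTwoTankParams(40.0, 20.0, theta=30.0), grid)
        assert rk.mrt_of_curve(e) == pytest.approx(90.0, abs=0.2)

    def test_near_equal_tanks_approach_equal_tank_model(self):
        grid = rk.TimeGrid(0.0, 0.1, 12000)
        tau1 = 50.0
        tau2 = 0.999 * tau1
        general = rk.e_unit_general(rk.GeneralTwoTankParams(tau1, tau2, theta=0.0), grid)
        # compare at equal mean: theta + tau1 + tau2 == 2 * tau_eq
        tau_eq = (tau1 + tau2) / 2.0
        equal = rk.e_unit(rk.RTDParams(tau_tank=tau_eq, theta=0.0), grid)
        rel = np.max(np.abs(general.density - equal.density)) / np.max(equal.density)
        assert rel < 0.01

    def test_tank_order_constraint_enforced(self):
        with pytest.raises(InvalidInputError):
            rk.GeneralTwoTankParams(20.0, 40.0)


class TestMRTIdentities:
    def test_feed_frame_identity(self):
        assert rk.mrt_from_tau_r(64.0, 0.389) == pytest.approx(292.5, abs=0.1)

    def test_large_ratio_limit_is_two_tau(self):
        assert rk.mrt_from_tau_r(1.0, 1e9) == pytest.approx(2.0, abs=1e-6)

    def test_blender2_identity(self):
        assert rk.mrt_from_tau_r(48.2, 0.378) == pytest.approx(224.0, abs=0.5)

    def test_inversion_matches_algebra(self):
        p = rk.params_from_mrt_r(292.5, 0.389)
        assert p.tau_tank == pytest.approx(64.0, abs=0.1)
        assert p.theta == pytest.approx(164.5, abs=0.1)

    def test_large_ratio_inversion_limit(self):
        p = rk.params_from_mrt_r(100.0, 1e9)
        assert p.theta == pytest.approx(0.0, abs=1e-6)
        assert p.tau_tank == pytest.approx(50.0, rel=1e-6)

    def test_round_trip(self):
        mrt = rk.mrt_from_tau_r(8.59, 0.378)
        assert mrt == pytest.approx(39.9, abs=0.1)
        p = rk.params_from_mrt_r(mrt, 0.378)
        assert p.tau_tank == pytest.approx(8.59, rel=1e-9)

    @given(
        tau=st.floats(0.5, 500.0),
        r=st.floats(1e-2, 1e4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inversion_is_exact_identity(self, tau, r):
        mrt = rk.mrt_from_tau_r(tau, r)
        p = rk.params_from_mrt_r(mrt, r)
        assert math.isclose(p.tau_tank, tau, rel_tol=1e-9)
        assert math.isclose(rk.mrt_from_tau_r(p.tau_tank, p.r_ratio), mrt, rel_tol=1e-9)


class TestErrorPropagation:
    def test_large_ratio_limit_doubles_tau_error(self):
        assert rk.epsilon_mrt(1.0, 1e9, eps_tau=3.0, eps_r=0.0) == pytest.approx(6.0, rel=1e-6)

    def test_zero_errors_propagate_to_zero(self):
        assert rk.epsilon_mrt(48.2, 0.378, 0.0, 0.0) == 0.0

    def test_direct_formula(self):
        tau, r, et, er = 48.2, 0.378, 1.0, 0.01
        expected = math.sqrt((2 + 1 / r) ** 2 * et**2 + (tau / r**2) ** 2 * er**2)
        assert rk.epsilon_mrt(tau, r, et, er) == pytest.approx(expected, rel=1e-12)

    def test_negative_eps_rejected(self):
        with pytest.raises(InvalidInputError):
            rk.epsilon_mrt(1.0, 1.0, -0.1, 0.0)


@given(
    tau=st.floats(2.0, 200.0),
    r=st.floats(0.05, 100.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_unit_model_normalization_and_moment_property(tau, r):
    """Every generated density integrates to 1 and has mean theta + 2*tau."""
    theta = tau / r
    params = rk.RTDParams(tau_tank=tau, theta=theta)
    grid = rk.default_grid(theta, tau, step=max((theta + 15 * tau) / 4000, 0.05))
    e = rk.e_unit(params, grid)
    assert e.integral() == pytest.approx(1.0, abs=TOL_NUMERIC)
    assert rk.mrt_of_curve(e) == pytest.approx(theta + 2 * tau, rel=1e-3)


@given(
    tau1=st.floats(5.0, 80.0),
    tau2=st.floats(5.0, 80.0),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_convolution_mrt_additivity_property(tau1, tau2):
    step = 0.25
    grid = rk.TimeGrid(0.0, step, int(15 * (tau1 + tau2) / step))
    conv = rk.convolve_rtd(rk.e_cstr(tau1, grid), rk.e_cstr(tau2, grid))
    assert abs(rk.mrt_of_curve(conv) - tau1 - tau2) < 2 * step
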