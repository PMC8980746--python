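"""Unit and property tests for the switched logistic growth model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsgrowth import (
    ControlSchedule,
    DelayFunction,
    GrowthParams,
    Trajectory,
    capacity,
    logistic_closed_form,
    rate,
    simulate,
    simulate_discrete,
)

from conftest import random_scenario


class TestGrowthParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            GrowthParams(0.0, 0.5, 1e8, 8e8)
        with pytest.raises(ValueError):
            GrowthParams(0.9, 0.5, -1e8, 8e8)
        with pytest.raises(ValueError):
            GrowthParams(np.nan, 0.5, 1e8, 8e8)

    def test_orientation_warns_but_accepts(self):
        p = GrowthParams(0.5, 0.9, 8e8, 1e8)  # benefit/cost reversed
        with pytest.warns(UserWarning):
            messages = p.check_orientation()
        assert len(messages) == 2
        assert GrowthParams(0.9, 0.45, 1e8, 8e8).check_orientation() == []


class TestDelayFunction:
    def test_hinge_evaluation(self):
        fn = DelayFunction.hinge(1e7, 5.0 / 9e7)
        assert fn(1e6) == 0.0  # no-delay window
        assert fn(1e7) == 0.0
        assert fn(1e8) == pytest.approx(5.0, rel=1e-12)
        # linear continuation above the last knot
        assert fn(4e8) == pytest.approx(5.0 / 9e7 * 3.9e8, rel=1e-12)

    def test_constant_and_zero(self):
        assert DelayFunction.constant(2.5)(1e3) == 2.5
        assert DelayFunction.constant(2.5)(1e10) == 2.5
        assert DelayFunction.zero()(5e8) == 0.0

    def test_invalid_knots_rejected(self):
        with pytest.raises(ValueError):
            DelayFunction(((1e7, 2.0), (1e8, 1.0)))  # decreasing delay
        with pytest.raises(ValueError):
            DelayFunction(((1e7, -1.0),))
        with pytest.raises(ValueError):
            DelayFunction(((1e8, 0.0), (1e7, 1.0)))  # densities not increasing

    @given(st.floats(min_value=1e3, max_value=1e10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nondecreasing_and_nonnegative(self, x):
        fn = DelayFunction(((1e6, 0.0), (1e7, 0.0), (1e8, 4.0), (5e8, 9.0)))
        assert fn(x) >= 0.0
        assert fn(1.01 * x) >= fn(x) - 1e-12


class TestControlSchedule:
    def test_mode_requirements(self):
        with pytest.raises(ValueError):
            ControlSchedule("external")  # t_induction missing
        with pytest.raises(ValueError):
            ControlSchedule("qs")  # alpha missing
        with pytest.raises(ValueError):
            ControlSchedule("external", t_induction=-1.0)
        with pytest.raises(ValueError):
            ControlSchedule("bogus")


class TestCapacity:
    def test_piecewise_values(self, params, zero_delay):
        ramp = DelayFunction.constant(4.0)
        # before induction
        assert capacity(2.0, 5.0, 1e7, params, ramp) == params.kappa0
        # midpoint of the ramp
        assert capacity(7.0, 5.0, 1e7, params, ramp) == pytest.approx(
            0.5 * (params.kappa0 + params.kappa1)
        )
        # after the ramp
        assert capacity(9.5, 5.0, 1e7, params, ramp) == params.kappa1
        # zero delay: step limit
        assert capacity(5.0 + 1e-12, 5.0, 1e6, params, zero_delay) == params.kappa1

    def test_continuity_at_ramp_edges(self, params):
        ramp = DelayFunction.constant(3.0)
        eps = 1e-9
        lo = capacity(5.0 - eps, 5.0, 1e7, params, ramp)
        at = capacity(5.0, 5.0, 1e7, params, ramp)
        hi = capacity(8.0 + eps, 5.0, 1e7, params, ramp)
        end = capacity(8.0, 5.0, 1e7, params, ramp)
        assert lo == pytest.approx(at, rel=1e-6)
        assert hi == pytest.approx(end, rel=1e-6)

    def test_rejects_nonfinite(self, params, zero_delay):
        with pytest.raises(ValueError):
            capacity(np.inf, 5.0, 1e7, params, zero_delay)
        with pytest.raises(ValueError):
            capacity(1.0, np.nan, 1e7, params, zero_delay)


class TestRate:
    def test_switch(self, params):
        assert rate(False, params) == params.lambda0
        assert rate(True, params) == params.lambda1
        same = GrowthParams(0.7, 0.7, 1e8, 1e8)
        assert rate(False, same) == rate(True, same)


def _rk4_logistic(n0, r, k, t_end, step=1e-3):
    """Brute-force RK4 oracle for the constant-parameter logistic ODE."""
    f = lambda n: r * n * (1.0 - n / k)
    n, t = n0, 0.0
    n_steps = int(round(t_end / step))
    for _ in range(n_steps):
        k1 = f(n)
        k2 = f(n + 0.5 * step * k1)
        k3 = f(n + 0.5 * step * k2)
        k4 = f(n + step * k3)
        n += step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return n


class TestClosedForm:
    def test_fixed_point_and_initial_condition(self):
        assert logistic_closed_form(1e8, 0.9, 1e8, 13.7) == pytest.approx(1e8)
        assert logistic_closed_form(3e5, 1.2, 1e9, 0.0) == pytest.approx(3e5)

    def test_matches_rk4_oracle(self):
        expected = _rk4_logistic(1e6, 0.5, 1e8, 10.0)
        got = logistic_closed_form(1e6, 0.5, 1e8, 10.0)
        assert abs(got / expected - 1.0) < 1e-6

    def test_monotone_toward_capacity(self):
        t = np.linspace(0, 30, 200)
        rising = logistic_closed_form(1e5, 0.8, 1e8, t)
        assert np.all(np.diff(rising) > 0) and rising[-1] < 1e8
        falling = logistic_closed_form(5e8, 0.8, 1e8, t)
        assert np.all(np.diff(falling) < 0) and falling[-1] > 1e8

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            logistic_closed_form(0.0, 0.5, 1e8, 1.0)
        with pytest.raises(ValueError):
            logistic_closed_form(1e6, 0.5, 0.0, 1.0)


class TestSimulate:
    def test_never_matches_closed_form(self, params, hinge_delay, hourly):
        traj = simulate(params, ControlSchedule.never(), hinge_delay, 1e6, hourly)
        expected = logistic_closed_form(1e6, params.lambda0, params.kappa0, hourly)
        np.testing.assert_allclose(traj.density, expected, rtol=1e-9)
        assert traj.activation_time is None
        assert np.all(traj.capacity == params.kappa0)

    def test_always_on_reduces_to_plain_logistic(self, params, zero_delay, hourly):
        traj = simulate(params, ControlSchedule.external(0.0), zero_delay, 1e6, hourly)
        expected = logistic_closed_form(1e6, params.lambda1, params.kappa1, hourly)
        np.testing.assert_allclose(traj.density, expected, rtol=1e-9)
        assert traj.activation_time == 0.0
        assert traj.activation_density == pytest.approx(1e6)

    def test_unreachable_threshold_never_fires(self, params, hinge_delay, hourly):
        t_long = np.arange(0.0, 49.0)
        traj = simulate(
            params, ControlSchedule.qs(2.0 * params.kappa0), hinge_delay, 1e6, t_long
        )
        assert traj.activation_time is None
        assert traj.density[-1] == pytest.approx(params.kappa0, rel=1e-6)
        oracle = simulate(
            params,
            ControlSchedule.qs(2.0 * params.kappa0),
            hinge_delay,
            1e6,
            t_long,
            method="fine_rk",
        )
        np.testing.assert_allclose(traj.density, oracle.density, rtol=1e-3)

    def test_qs_activates_at_threshold_density(self, params, hinge_delay, hourly):
        traj = simulate(params, ControlSchedule.qs(5e7), hinge_delay, 1e6, hourly)
        assert traj.activation_density == pytest.approx(5e7)
        # density at the activation time equals the threshold
        at = logistic_closed_form(1e6, params.lambda0, params.kappa0, traj.activation_time)
        assert at == pytest.approx(5e7, rel=1e-9)

    def test_parameter_collapse_makes_schedules_identical(self, hourly):
        p = GrowthParams(0.8, 0.8, 2e8, 2e8)
        fn = DelayFunction.hinge(1e7, 3.0 / 1e8)
        trajs = [
            simulate(p, sched, fn, 1e6, hourly).density
            for sched in (
                ControlSchedule.never(),
                ControlSchedule.external(4.0),
                ControlSchedule.qs(5e7),
            )
        ]
        np.testing.assert_allclose(trajs[0], trajs[1], rtol=1e-9)
        np.testing.assert_allclose(trajs[0], trajs[2], rtol=1e-9)

    def test_delay_to_zero_limit_recovers_instantaneous_switch(
        self, params, hourly
    ):
        sched = ControlSchedule.external(5.0)
        instant = simulate(params, sched, DelayFunction.zero(), 1e6, hourly)
        sup_norms = []
        for scale in (2.0, 0.5, 0.1, 0.01):
            fn = DelayFunction.hinge(1e7, scale / 9e7)
            traj = simulate(params, sched, fn, 1e6, hourly)
            sup_norms.append(np.max(np.abs(traj.density / instant.density - 1.0)))
        assert all(a > b for a, b in zip(sup_norms, sup_norms[1:]))
        assert sup_norms[-1] < 1e-3

    def test_piecewise_closed_form_agrees_with_rk4_oracle(self, hourly):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(10):
            p, sched, fn, n0 = random_scenario(rng)
            a = simulate(p, sched, fn, n0, hourly)
            b = simulate(p, sched, fn, n0, hourly, method="fine_rk")
            worst = max(worst, np.max(np.abs(a.density / b.density - 1.0)))
        assert worst < 1e-3

    def test_monotone_approach_to_new_capacity(self, params, hinge_delay):
        t = np.linspace(0.0, 36.0, 145)
        traj = simulate(params, ControlSchedule.external(5.0), hinge_delay, 1e6, t)
        delay = hinge_delay(traj.activation_density)
        after = t > traj.activation_time + delay
        gaps = np.abs(traj.density[after] - params.kappa1)
        assert np.all(np.diff(gaps) <= 1e-9 * params.kappa1)

    def test_capacity_series_matches_ramp(self, params, hinge_delay, hourly):
        traj = simulate(params, ControlSchedule.external(8.0), hinge_delay, 1e6, hourly)
        delay = hinge_delay(traj.activation_density)
        assert np.all(traj.capacity[hourly < 8.0] == params.kappa0)
        assert np.all(traj.capacity[hourly > 8.0 + delay] == params.kappa1)

    def test_invalid_inputs(self, params, zero_delay):
        with pytest.raises(ValueError):
            simulate(params, ControlSchedule.never(), zero_delay, 1e6, [0.0, 1.0], method="nope")
        with pytest.raises(ValueError):
            simulate(params, ControlSchedule.never(), zero_delay, 1e6, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(params, ControlSchedule.never(), zero_delay, -5.0, [0.0, 1.0])
        with pytest.raises(ValueError):
            simulate(params, ControlSchedule.never(), zero_delay, 1e6, [1.0, 2.0])


class TestSimulateDiscrete:
    def test_exact_for_constant_parameters(self, params, zero_delay):
        for dt in (0.25, 1.0, 3.0):
            traj = simulate_discrete(params, ControlSchedule.never(), zero_delay, 1e6, dt, 24.0)
            expected = logistic_closed_form(1e6, params.lambda0, params.kappa0, traj.times)
            np.testing.assert_allclose(traj.density, expected, rtol=1e-12)

    def test_fixed_point(self, params, zero_delay):
        traj = simulate_discrete(
            params, ControlSchedule.never(), zero_delay, params.kappa0, 1.0, 24.0
        )
        np.testing.assert_allclose(traj.density, params.kappa0, rtol=1e-12)

    def test_grid_refinement(self, params, hinge_delay):
        coarse = simulate_discrete(
            params, ControlSchedule.external(5.0), hinge_delay, 1e6, 1.0, 24.0
        )
        fine = simulate_discrete(
            params, ControlSchedule.external(5.0), hinge_delay, 1e6, 0.01, 24.0
        )
        sub = np.isin(np.round(fine.times, 9), np.round(coarse.times, 9))
        assert np.max(np.abs(coarse.density / fine.density[sub] - 1.0)) < 1e-2

    def test_euler_scheme_converges_to_closed_form(self, params, zero_delay):
        closed = simulate_discrete(params, ControlSchedule.never(), zero_delay, 1e6, 1.0, 24.0)
        euler = simulate_discrete(
            params, ControlSchedule.never(), zero_delay, 1e6, 0.001, 24.0, scheme="euler"
        )
        sub = np.isin(np.round(euler.times, 9), np.round(closed.times, 9))
        np.testing.assert_allclose(euler.density[sub], closed.density, rtol=2e-3)

    def test_invalid_dt_and_horizon(self, params, zero_delay):
        with pytest.raises(ValueError):
            simulate_discrete(params, ControlSchedule.never(), zero_delay, 1e6, -1.0, 24.0)
        with pytest.raises(ValueError):
            simulate_discrete(params, ControlSchedule.never(), zero_delay, 1e6, 1.0, 24.5)


class TestTrajectory:
    def test_validation(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.array([1e6]), np.array([1e8, 1e8]))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.array([1e6, -1.0]), np.array([1e8, 1e8]))

    def test_csv_round_trip(self, params, hinge_delay, hourly, tmp_path):
        traj = simulate(params, ControlSchedule.external(5.0), hinge_delay, 1e6, hourly)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        np.testing.assert_allclose(back.density, traj.density, rtol=1e-12)
        assert back.activation_time == pytest.approx(traj.activation_time)
        assert back.activation_density == pytest.approx(traj.activation_density)
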