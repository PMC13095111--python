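"""Rate model, forward steering evaluation, and the fly softplus model."""

import numpy as np
import pytest

from cxsteer import (ActivationParams, build_fly, build_uniform,
                     compass_rates, fly_steering, goal_rates, sigmoid_rate,
                     softplus_rate, steering_command)


class TestSigmoidRate:
    def test_midpoint_and_value(self):
        p = ActivationParams()
        assert sigmoid_rate(0.6, p) == pytest.approx(0.5)
        assert sigmoid_rate(1.1, p) == pytest.approx(1 / (1 + np.exp(-1.0)))

    def test_saturation_and_monotonicity(self):
        p = ActivationParams()
        assert sigmoid_rate(50.0, p) == pytest.approx(1.0)
        assert sigmoid_rate(-50.0, p) == pytest.approx(0.0, abs=1e-9)
        x = np.linspace(-3, 3, 100)
        assert np.all(np.diff(sigmoid_rate(x, p)) > 0)

    def test_slope_must_be_positive(self):
        with pytest.raises(ValueError):
            ActivationParams(slope=0.0)


class TestPopulationRates:
    def test_compass_peak_and_trough(self):
        spec = build_uniform(3)
        r = compass_rates(120.0, spec)           # heading at neuron 1's PFD
        assert r[1] == pytest.approx(sigmoid_rate(1.0, spec.activation))
        r = compass_rates(300.0, spec)           # antipode of neuron 1
        assert r[1] == pytest.approx(sigmoid_rate(-1.0, spec.activation))

    def test_all_rates_strictly_positive_everywhere(self):
        spec = build_uniform(5)
        H = np.arange(0.0, 360.0, 1.0)
        assert np.all(compass_rates(H, spec) > 0)
        assert np.all(compass_rates(H, spec) < 1)

    def test_goal_rates_rotation_equivariant(self):
        spec = build_uniform(8)
        r0 = goal_rates(37.0, spec)
        shifted = build_uniform(8)
        shifted.goal_dirs = shifted.goal_dirs + 55.0
        r1 = goal_rates(37.0 + 55.0, shifted)
        np.testing.assert_allclose(r0, r1, atol=1e-12)


class TestSteeringCommand:
    def test_zero_at_goal_for_uniform(self):
        """Exact balance at the circuit's symmetry points (compass PFDs and
        goal directions); elsewhere the discreteness residual is a small
        fraction of the command amplitude."""
        for n in (3, 8):
            spec = build_uniform(n)
            for h in (0.0, 360.0 / (2 * n)):
                assert steering_command(h, h, spec) == pytest.approx(0.0, abs=1e-12)
            for h in (45.0 + 3.0 / n, 211.0):
                amp = np.max(np.abs(steering_command(
                    np.arange(0.0, 360.0, 1.0), h, spec)))
                assert abs(steering_command(h, h, spec)) < 0.05 * amp

    @pytest.mark.parametrize("n", [3, 5, 8, 21])
    def test_uniform_invariance_under_spacing_shifts(self, n):
        """Circulant wiring: shifting heading and goal by the population
        spacing 360/N leaves the command exactly unchanged."""
        spec = build_uniform(n)
        H = np.arange(0.0, 360.0, 15.0)
        base = steering_command(H, H + 40.0, spec)
        shifted = steering_command(H + 360.0 / n, H + 40.0 + 360.0 / n, spec)
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_equivariance_under_circuit_rotation(self):
        """Rotating every tuned direction together with both inputs leaves
        the command unchanged for any rotation (cosine-difference tuning)."""
        spec = build_uniform(5)
        rot = build_uniform(5)
        delta = 17.3
        rot.compass_pfds = rot.compass_pfds + delta
        rot.goal_dirs = rot.goal_dirs + delta
        H = np.arange(0.0, 360.0, 30.0)
        np.testing.assert_allclose(
            steering_command(H, H + 75.0, spec),
            steering_command(H + delta, H + 75.0 + delta, rot), atol=1e-12)

    def test_single_stable_zero_crossing_at_goal(self):
        """Brute-force 1-deg scan: the only stable equilibrium is the goal."""
        spec = build_uniform(3)
        H = np.arange(0.0, 360.0, 1.0)
        cmd = steering_command(H, 60.0, spec)
        # stable crossings: command passes from positive to negative
        stable = [h for i, h in enumerate(H)
                  if cmd[i] > 0 >= cmd[(i + 1) % len(H)]]
        assert len(stable) == 1
        assert abs(stable[0] - 60.0) <= 1.5   # crossing lies in [59, 60]

    def test_command_linear_in_gain(self):
        spec = build_uniform(3)
        c1 = steering_command(10.0, 60.0, spec)
        c2 = steering_command(10.0, 60.0, spec.with_gain(2.0 * spec.gain))
        assert c2 == pytest.approx(2.0 * c1)


class TestFlyModel:
    def test_softplus_at_shift(self):
        fly = build_fly().fly
        assert softplus_rate(0.7, fly) == pytest.approx(29.23 * np.log(2.0))

    def test_command_vanishes_on_diagonal(self):
        fly = build_fly().fly
        amp = np.abs([fly_steering(h, 0.0, fly) for h in range(0, 360, 5)]).max()
        for h in (0.0, 33.0, 120.0, 275.0):
            assert abs(fly_steering(h, h, fly)) < 1e-2 * amp

    def test_rotational_invariance_grid(self):
        """Command depends only on wrap(H - G) over a 36x36 grid, up to the
        small discreteness ripple of the 45-deg PFL3 spacing."""
        fly = build_fly().fly
        a = np.arange(0.0, 360.0, 10.0)
        cmd = fly_steering(a[:, None], a[None, :], fly)
        amp = np.max(np.abs(cmd))
        for k in range(36):
            diag = np.array([cmd[i, (i + k) % 36] for i in range(36)])
            assert np.ptp(diag) < 0.02 * amp

    def test_antisymmetric_about_heading(self):
        fly = build_fly().fly
        for h in (0.0, 100.0):
            for d in (10.0, 45.0, 120.0):
                assert fly_steering(h, h + d, fly) == pytest.approx(
                    -fly_steering(h, h - d, fly), abs=1e-4)

    def test_negative_feedback_toward_goal(self):
        """Positive command (CCW) when the goal lies counter-clockwise."""
        fly = build_fly().fly
        assert fly_steering(-10.0, 0.0, fly) > 0
        assert fly_steering(10.0, 0.0, fly) < 0
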