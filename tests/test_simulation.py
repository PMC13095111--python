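"""Goal-trace protocols, closed-loop integration, gain tuning, plateaus."""

import numpy as np
import pytest
from scipy.special import iv

from cxsteer import (Trajectory, build_uniform, detect_stable_headings,
                     random_walk_goal, run_closed_loop, smooth_turn_goal,
                     step_change_goal, tracking_error, tune_gain, wrap_diff)
from cxsteer.simulation import VON_MISES_KAPPA


class TestRandomWalkGoal:
    def test_high_concentration_limit_is_constant(self):
        goal = random_walk_goal(duration=5.0, kappa=1e9, rng=0, start=77.0)
        assert np.max(np.abs(wrap_diff(goal - 77.0))) < 0.1

    def test_increment_statistics_match_von_mises(self):
        """Circular s.d. of raw increments vs the Bessel-function closed
        form sqrt(-2 ln(I1(k)/I0(k)))."""
        rng = np.random.default_rng(42)
        inc = np.degrees(rng.vonmises(0.0, VON_MISES_KAPPA, size=100_000))
        r = np.abs(np.mean(np.exp(1j * np.radians(inc))))
        sd = np.degrees(np.sqrt(-2.0 * np.log(r)))
        expected = np.degrees(np.sqrt(-2.0 * np.log(
            iv(1, VON_MISES_KAPPA) / iv(0, VON_MISES_KAPPA))))
        assert sd == pytest.approx(expected, rel=0.02)
        assert abs(np.mean(inc)) < 0.2   # mu = 0

    def test_deterministic_given_seed(self):
        a = random_walk_goal(duration=3.0, rng=5)
        b = random_walk_goal(duration=3.0, rng=5)
        np.testing.assert_array_equal(a, b)

    def test_holds_each_increment(self):
        goal = random_walk_goal(duration=2.0, dt=0.01, rng=1)
        assert np.ptp(goal[:100]) == 0.0    # constant within one period


class TestDeterministicProtocols:
    def test_smooth_turn_ramp(self):
        goal = smooth_turn_goal(duration=80.0, dt=0.01)
        assert goal[0] == 0.0
        assert abs(wrap_diff(goal[-1])) < 1.0
        mid = goal[len(goal) // 2]
        assert abs(wrap_diff(mid - 360.0)) < 1.0
        rate = np.abs(wrap_diff(np.diff(goal))) / 0.01
        assert np.max(rate) <= 50.0    # slower than the tuned circuits

    def test_step_change_values_and_validation(self):
        goal = step_change_goal(60.0, duration=20.0, hold=5.0)
        assert set(np.unique(goal)) == {0.0, 60.0}
        assert goal[0] == 0.0
        assert goal[700] == 60.0      # t = 7 s falls in the stepped segment
        with pytest.raises(ValueError):
            step_change_goal(45.0)


class TestClosedLoop:
    def test_equilibrium_holds(self, tuned_cache):
        spec = tuned_cache(build_uniform(8), "u8")
        # goal at a represented direction: the balance is exact
        traj = run_closed_loop(spec, np.full(300, 22.5), initial_heading=22.5)
        assert np.max(np.abs(traj.command)) < 1e-6
        assert np.max(np.abs(wrap_diff(traj.heading - 22.5))) < 1e-6
        # generic goal: the discreteness residual moves the heading < 2 deg
        traj = run_closed_loop(spec, np.full(600, 40.0), initial_heading=40.0)
        assert np.max(np.abs(wrap_diff(traj.heading - 40.0))) < 2.0

    def test_converges_from_90_degrees_away(self, tuned_cache):
        spec = tuned_cache(build_uniform(3), "u3")
        traj = run_closed_loop(spec, np.full(600, 0.0), initial_heading=90.0)
        assert abs(wrap_diff(traj.heading[-1])) < 5.0

    def test_rule4_breaker_settles_at_antipode(self, rule_breakers,
                                               tuned_cache):
        spec = tuned_cache(rule_breakers["rule4"], "rule4")
        for h0 in (40.0, 150.0, 250.0):
            traj = run_closed_loop(spec, np.zeros(1200), initial_heading=h0)
            assert abs(abs(wrap_diff(traj.heading[-1])) - 180.0) < 5.0

    def test_step_bound(self, tuned_cache):
        spec = tuned_cache(build_uniform(3), "u3")
        goal = step_change_goal(90.0, duration=10.0)
        traj = run_closed_loop(spec, goal)
        dh = np.abs(wrap_diff(np.diff(traj.heading)))
        assert np.max(dh) <= np.max(np.abs(traj.command)) * 0.01 + 1e-12

    def test_deterministic(self, tuned_cache):
        spec = tuned_cache(build_uniform(3), "u3")
        goal = random_walk_goal(duration=5.0, rng=9)
        a = run_closed_loop(spec, goal)
        b = run_closed_loop(spec, goal)
        np.testing.assert_array_equal(a.heading, b.heading)

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(t=np.zeros(3), goal=np.zeros(3),
                       heading=np.zeros(3), command=np.zeros(2))


class TestTuneGain:
    @pytest.mark.parametrize("builder_key", ["u3", "u21", "fly"])
    def test_peak_step_rate_in_band(self, builder_key, tuned_cache,
                                    fly_circuit):
        from cxsteer.simulation import _peak_step_rate
        spec = {"u3": build_uniform(3), "u21": build_uniform(21),
                "fly": fly_circuit}[builder_key]
        tuned = tuned_cache(spec, builder_key)
        assert 50.0 <= _peak_step_rate(tuned) <= 60.0

    def test_gain_scales_with_band(self):
        spec = build_uniform(3)
        k1 = tune_gain(spec, target_rate_band=(50.0, 60.0))
        k2 = tune_gain(spec, target_rate_band=(100.0, 120.0))
        assert k2 / k1 == pytest.approx(2.0, rel=0.1)

    def test_tracking_similar_across_sizes(self, tuned_cache):
        goal = random_walk_goal(duration=30.0, rng=11)
        eps = [tracking_error(run_closed_loop(
            tuned_cache(build_uniform(n), f"u{n}"), goal))
            for n in (3, 21)]
        assert abs(eps[0] - eps[1]) < 10.0


class TestStableHeadingDetection:
    def test_constant_trace_single_plateau(self):
        n = 1000
        traj = Trajectory(t=np.arange(n) * 0.01, goal=np.zeros(n),
                          heading=np.full(n, 100.0), command=np.zeros(n))
        rep = detect_stable_headings(traj)
        assert rep.headings.size == 1
        assert rep.headings[0] == pytest.approx(100.0, abs=2.5)
        assert rep.dwell_fractions[0] == pytest.approx(1.0)

    def test_tracker_has_no_plateaus(self, tuned_cache):
        spec = tuned_cache(build_uniform(8), "u8")
        traj = run_closed_loop(spec, smooth_turn_goal(40.0))
        assert detect_stable_headings(traj).headings.size == 0
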