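"""Event scheduling, behavioural rules and the event-driven engine."""

import math

import numpy as np
import pytest
from scipy import stats

from stochflock.model_core import AgentState, ModelParams, wrap_angle
from stochflock.simulator import (
    advance_positions,
    apply_alignment,
    apply_attraction,
    apply_collision_avoidance,
    apply_spontaneous_turn,
    micro_step_length,
    run_simulation,
    sample_next_event,
)


def make_states(positions, headings=None, speeds=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    headings = np.zeros(n) if headings is None else np.asarray(headings, dtype=float)
    speeds = np.ones(n) if speeds is None else np.asarray(speeds, dtype=float)
    return [
        AgentState(id=i, x=positions[i], s=speeds[i], heading=headings[i])
        for i in range(n)
    ]


class TestScheduler:
    def test_degenerate_mixture_is_all_turns(self):
        p = ModelParams(N=5, K=2, k=1, r_p=0.0, r_c=0.0, r_s=1.0)
        rng = np.random.default_rng(0)
        assert all(
            sample_next_event(p, rng)[2] == "turn" for _ in range(100)
        )

    def test_zero_total_rate_rejected(self):
        p = ModelParams(N=5, K=2, k=1, r_p=0.0, r_c=0.0, r_s=0.0)
        with pytest.raises(ValueError):
            sample_next_event(p, np.random.default_rng(0))

    def test_mean_waiting_time(self):
        # N = 10, all rates 1: Lambda = 30, mean dt = 1/30 within 3 s.e.
        p = ModelParams(N=10, K=3, k=1, r_p=1.0, r_c=1.0, r_s=1.0)
        rng = np.random.default_rng(1)
        n = 10_000
        dts = np.array([sample_next_event(p, rng)[0] for _ in range(n)])
        se = (1 / 30) / math.sqrt(n)  # exponential sd = mean
        assert abs(dts.mean() - 1 / 30) < 3 * se

    def test_event_type_proportions(self):
        # Rates 2:1:1 -> probabilities 0.5, 0.25, 0.25 within 3 s.e.
        p = ModelParams(N=10, K=3, k=1, r_p=2.0, r_c=1.0, r_s=1.0)
        rng = np.random.default_rng(2)
        n = 10_000
        types = [sample_next_event(p, rng)[2] for _ in range(n)]
        for etype, prob in [("align", 0.5), ("attract", 0.25), ("turn", 0.25)]:
            freq = types.count(etype) / n
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < 3 * se

    def test_focal_uniform(self):
        p = ModelParams(N=4, K=2, k=1)
        rng = np.random.default_rng(3)
        n = 8000
        focals = np.array([sample_next_event(p, rng)[1] for _ in range(n)])
        counts = np.bincount(focals, minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01


class TestAlignment:
    def test_single_partner_exact_copy(self):
        states = make_states([[0, 0], [1, 0]], headings=[0.0, 1.3], speeds=[1.0, 2.0])
        p = ModelParams(N=2, K=1, k=1)
        out = apply_alignment(0, [1], states, p)
        assert out.heading == pytest.approx(1.3)
        assert out.s == pytest.approx(2.0)

    def test_multiple_partners_average(self):
        states = make_states(
            [[0, 0], [1, 0], [0, 1]],
            headings=[2.0, 0.0, math.pi / 2],
            speeds=[1.0, 1.0, 3.0],
        )
        p = ModelParams(N=3, K=2, k=2)
        out = apply_alignment(0, [1, 2], states, p)
        assert out.heading == pytest.approx(math.pi / 4)
        assert out.s == pytest.approx(2.0)

    def test_empty_partners_noop(self):
        states = make_states([[0, 0], [1, 0]], headings=[0.7, 1.3], speeds=[1.5, 2.0])
        p = ModelParams(N=2, K=1, k=1)
        out = apply_alignment(0, [], states, p)
        assert out.heading == pytest.approx(0.7) and out.s == pytest.approx(1.5)

    def test_antipodal_partners_keep_heading(self):
        states = make_states(
            [[0, 0], [1, 0], [0, 1]],
            headings=[0.7, math.pi / 2, -math.pi / 2],
        )
        p = ModelParams(N=3, K=2, k=2)
        out = apply_alignment(0, [1, 2], states, p)
        assert out.heading == pytest.approx(0.7)


class TestAttraction:
    def test_direct_pursuit(self):
        states = make_states([[0, 0], [2, 0]])
        p = ModelParams(N=2, K=1, k=1)
        out = apply_attraction(0, [1], states, p)
        assert out.heading == pytest.approx(0.0)

    def test_at_centroid_keeps_heading_resets_speed(self):
        states = make_states([[1, 0], [0, 0], [2, 0]], headings=[0.9, 0, 0],
                             speeds=[1.7, 1, 1])
        p = ModelParams(N=3, K=2, k=2)
        out = apply_attraction(0, [1, 2], states, p)
        assert out.heading == pytest.approx(0.9)
        assert out.s == pytest.approx(p.s0)

    def test_centroid_distance_speed_law(self):
        # Partners at (1,1), (3,1); focal (2,0): centroid (2,1), d = 1,
        # heading pi/2, speed = min(s_max, s0 * d / epsilon) = 1.
        states = make_states([[2, 0], [1, 1], [3, 1]])
        p = ModelParams(N=3, K=2, k=2, epsilon=1.0, s0=1.0, s_max=2.0)
        out = apply_attraction(0, [1, 2], states, p)
        assert out.heading == pytest.approx(math.pi / 2)
        assert out.s == pytest.approx(1.0)

    def test_speed_clamped_at_s_max(self):
        states = make_states([[0, 0], [10, 0]])
        p = ModelParams(N=2, K=1, k=1, s_max=2.0)
        out = apply_attraction(0, [1], states, p)
        assert out.s == pytest.approx(2.0)


class TestSpontaneousTurn:
    def test_zero_variance_limit(self):
        p = ModelParams(N=2, K=1, k=1, sigma_a2=0.0, sigma_s2=0.0)
        st = AgentState(0, [0.0, 0.0], 0.5, 1.1)
        rng = np.random.default_rng(0)
        out = apply_spontaneous_turn(st, p, rng)
        assert out.heading == pytest.approx(1.1)
        assert out.s == pytest.approx(p.s0)

    def test_heading_statistics(self):
        # Circular mean stays at the original heading and circular variance
        # approaches sigma_a2 (small-variance regime).
        p = ModelParams(N=2, K=1, k=1, sigma_a2=0.04)
        st = AgentState(0, [0.0, 0.0], 1.0, 2.0)
        rng = np.random.default_rng(4)
        hs = np.array(
            [apply_spontaneous_turn(st, p, rng).heading for _ in range(10_000)]
        )
        R = np.hypot(np.cos(hs).sum(), np.sin(hs).sum()) / hs.size
        mean_h = math.atan2(np.sin(hs).sum(), np.cos(hs).sum())
        assert abs(wrap_angle(mean_h - 2.0)) < 3 * math.sqrt(0.04 / hs.size)
        circ_var = -2 * math.log(R)  # wrapped normal: R = exp(-sigma^2/2)
        assert circ_var == pytest.approx(0.04, rel=0.1)

    def test_speed_statistics(self):
        p = ModelParams(N=2, K=1, k=1, sigma_s2=0.01, s_min=0.0)
        st = AgentState(0, [0.0, 0.0], 1.0, 0.0)
        rng = np.random.default_rng(5)
        ss = np.array([apply_spontaneous_turn(st, p, rng).s for _ in range(10_000)])
        se = 0.1 / math.sqrt(ss.size)
        assert abs(ss.mean() - p.s0) < 3 * se
        assert ss.min() >= p.s_min and ss.max() <= p.s_max


class TestCollisionAvoidance:
    def test_out_of_range_unchanged(self):
        p = ModelParams(N=2, K=1, k=1)
        states = make_states([[0, 0], [10 * p.d_c, 0]], headings=[0.0, math.pi])
        out = apply_collision_avoidance(states, p, 0.01)
        assert out[0].heading == 0.0 and out[1].heading == pytest.approx(math.pi)
        assert out[0].s == 1.0

    def test_head_on_pair_turns_away_and_slows(self):
        p = ModelParams(N=2, K=1, k=1, d_c=0.5, avoid_turn_rate=math.pi,
                        avoid_slow_factor=0.5, s_min=0.1)
        dt = 0.01
        states = make_states(
            [[0, 0], [0.3, 0]], headings=[0.0, math.pi], speeds=[1.0, 1.0]
        )
        out = apply_collision_avoidance(states, p, dt)
        # Agent 0 faces +x, away-direction is -x (pi): turn by rate*dt.
        assert abs(abs(out[0].heading)) == pytest.approx(math.pi * dt)
        assert abs(wrap_angle(out[1].heading - math.pi)) == pytest.approx(
            math.pi * dt
        )
        assert out[0].s == pytest.approx(0.5)

    def test_turn_capped_at_facing_away(self):
        p = ModelParams(N=2, K=1, k=1, d_c=0.5, avoid_turn_rate=1000.0)
        states = make_states([[0, 0], [0.3, 0]], headings=[math.pi - 0.2, 0.5])
        out = apply_collision_avoidance(states, p, 0.01)
        # Already nearly facing away: rotates exactly onto the away bearing.
        assert abs(wrap_angle(out[0].heading - math.pi)) < 1e-9

    def test_coincident_agents_no_crash(self):
        p = ModelParams(N=2, K=1, k=1, d_c=0.5)
        states = make_states([[0, 0], [0, 0]], headings=[0.3, 0.3])
        out = apply_collision_avoidance(states, p, 0.01)
        # Counter-clockwise rotation by rate*dt for both.
        assert out[0].heading == pytest.approx(0.3 + p.avoid_turn_rate * 0.01)

    def test_speed_clamped_below_by_s_min(self):
        p = ModelParams(N=2, K=1, k=1, d_c=0.5, avoid_slow_factor=0.5, s_min=0.4)
        states = make_states([[0, 0], [0.1, 0]], speeds=[0.5, 0.5])
        out = apply_collision_avoidance(states, p, 0.01)
        assert out[0].s == pytest.approx(0.4)


class TestAdvancePositions:
    def test_zero_dt_identity(self):
        states = make_states([[1, 2], [3, 4]])
        out = advance_positions(states, 0.0)
        np.testing.assert_array_equal(out[0].x, [1, 2])

    def test_hand_kinematics(self):
        states = make_states([[0, 0]], headings=[0.0], speeds=[2.0])
        out = advance_positions(states, 0.5)
        np.testing.assert_allclose(out[0].x, [1.0, 0.0])

    def test_two_half_steps_equal_one(self):
        rng = np.random.default_rng(6)
        states = make_states(
            rng.normal(size=(5, 2)),
            headings=rng.uniform(-3, 3, 5),
            speeds=rng.uniform(0.5, 2, 5),
        )
        once = advance_positions(states, 0.4)
        twice = advance_positions(advance_positions(states, 0.2), 0.2)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.x, b.x, atol=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            advance_positions(make_states([[0, 0]]), -0.1)


class TestRunSimulation:
    def test_same_seed_bit_identical(self):
        p = ModelParams(N=8, K=3, k=1)
        t1 = run_simulation(p, 10.0, 0.5, seed=42)
        t2 = run_simulation(p, 10.0, 0.5, seed=42)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.speeds, t2.speeds)
        np.testing.assert_array_equal(t1.headings, t2.headings)
        assert t1.events == t2.events

    def test_event_times_strictly_increase(self):
        p = ModelParams(N=6, K=2, k=1)
        traj = run_simulation(p, 20.0, 0.5, seed=1)
        times = [ev.t for ev in traj.events]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_interevent_gaps_exponential(self):
        # KS test of gaps against Exponential(Lambda) at alpha = 0.01.
        p = ModelParams(N=10, K=3, k=1, r_p=1.0, r_c=1.0, r_s=1.0)
        traj = run_simulation(p, 350.0, 5.0, seed=9)
        times = np.array([ev.t for ev in traj.events])
        assert times.size > 10_000
        gaps = np.diff(times[:10_001])
        lam = p.total_rate
        assert stats.kstest(gaps, "expon", args=(0, 1 / lam)).pvalue > 0.01

    def test_single_agent_random_walk(self):
        # No neighbours exist: every align/attract fails (empty partners)
        # and only spontaneous turns change the state.
        p = ModelParams(N=1, K=1, k=1)
        traj = run_simulation(p, 30.0, 0.5, seed=3)
        assert all(ev.partners == () for ev in traj.events)
        assert any(ev.etype == "turn" for ev in traj.events)
        assert np.linalg.norm(traj.positions[-1, 0] - traj.positions[0, 0]) > 0

    def test_speed_bounds_at_all_samples(self):
        p = ModelParams(N=12, K=4, k=2)
        traj = run_simulation(p, 30.0, 0.5, seed=5)
        assert np.all(traj.speeds >= p.s_min - 1e-12)
        assert np.all(traj.speeds <= p.s_max + 1e-12)

    def test_minimal_model_constant_speed(self):
        p = ModelParams(N=10, K=3, k=1, minimal=True)
        traj = run_simulation(p, 20.0, 0.5, seed=7)
        np.testing.assert_allclose(traj.speeds, p.s0)

    def test_aligned_pair_is_fixed_point(self):
        # Two mutually visible agents with equal headings, alignment only:
        # copying an identical heading changes nothing.
        p = ModelParams(
            N=2, K=1, k=1, r_s=0.0, r_c=0.0, r_p=1.0, minimal=True
        )
        init = (
            np.array([[0.0, 0.0], [0.0, 1.0]]),
            np.array([p.s0, p.s0]),
            np.array([0.4, 0.4]),
        )
        traj = run_simulation(p, 10.0, 0.5, seed=11, init=init)
        np.testing.assert_allclose(traj.headings, 0.4)

    def test_snapshot_grid_shape(self):
        p = ModelParams(N=4, K=2, k=1)
        traj = run_simulation(p, 10.0, 0.5, seed=0)
        assert traj.n_samples == 21
        assert traj.positions.shape == (21, 4, 2)
        np.testing.assert_allclose(np.diff(traj.sample_times), 0.5)

    def test_partner_sets_respect_k(self):
        p = ModelParams(N=10, K=5, k=3)
        traj = run_simulation(p, 20.0, 0.5, seed=13)
        for ev in traj.events:
            assert len(ev.partners) <= 3
            assert ev.focal not in ev.partners
            if ev.etype == "turn":
                assert ev.partners == ()

    def test_micro_step_respects_scales(self):
        p = ModelParams(N=2, K=1, k=1, epsilon=0.05, s_max=2.0)
        assert micro_step_length(p) == pytest.approx(0.05 / 20.0)
        assert micro_step_length(ModelParams()) == pytest.approx(0.01)
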