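"""Asynchronous event engine: scheduling, updates, full-run contracts."""

import math

import numpy as np
import pytest

from burstschool import (FishState, ModelParams, Simulation, init_circle,
                         init_ellipse, kick_update, pair_interaction,
                         relative_state, run_simulation)


def make_sim(states, params, seed=0):
    return Simulation(params, states, seed=seed)


class TestKickUpdate:
    def test_unperturbed_kick_continues_straight(self, rng):
        p = ModelParams(gamma_att=0.0, gamma_ali=0.0, gamma_r=0.0, n_fish=1)
        st = FishState(0, np.zeros(2), 0.4, 0.0, 1.2)
        new = kick_update(st, [], rng, p)
        assert new.heading == st.heading
        assert new.t_kick == pytest.approx(1.2)
        assert np.allclose(new.pos_kick,
                           1.2 * np.array([math.cos(0.4), math.sin(0.4)]))

    def test_social_contribution_adds_to_heading(self, rng):
        p = ModelParams(gamma_att=0.6, gamma_ali=0.0, gamma_r=0.0, n_fish=2)
        st = FishState(0, np.zeros(2), 0.0, 0.0, 1.0)
        new = kick_update(st, [(1, 0.9)], rng, p)
        assert new.heading == pytest.approx(0.9)

    def test_noise_increment_scale(self):
        # isolated fish: heading increments are gamma_r * N(0, 1)
        p = ModelParams(gamma_att=0.0, gamma_ali=0.0, gamma_r=0.2, n_fish=1)
        sim = make_sim([FishState(0, np.zeros(2), 0.0, 0.0, 1.0)], p, seed=4)
        increments = []
        prev = 0.0
        for _ in range(10_000):
            sim.step_event()
            dh = math.remainder(sim.heading[0] - prev, 2 * math.pi)
            increments.append(dh)
            prev = sim.heading[0]
        std = np.std(increments)
        assert abs(std - 0.2) / 0.2 < 0.05
        assert abs(np.mean(increments)) < 0.01


class TestEventScheduling:
    def params(self, n):
        return ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=n)

    def test_earliest_kick_processed_first(self):
        states = [FishState(0, np.zeros(2), 0.0, 0.0, 1.1),
                  FishState(1, np.array([2.0, 0.0]), 0.0, 0.0, 0.9)]
        sim = make_sim(states, self.params(2))
        info = sim.step_event()
        assert info["fish_id"] == 1
        assert info["t_kick"] == pytest.approx(0.9)

    def test_simultaneous_kicks_lowest_id_first(self):
        states = [FishState(0, np.zeros(2), 0.0, 0.0, 1.0),
                  FishState(1, np.array([2.0, 0.0]), 0.0, 0.0, 1.0)]
        sim = make_sim(states, self.params(2))
        assert sim.step_event()["fish_id"] == 0

    def test_event_queue_conserved(self):
        states = [FishState(i, np.array([float(i), 0.0]), 0.0, 0.0,
                            1.0 + 0.1 * i) for i in range(4)]
        sim = make_sim(states, self.params(4))
        for _ in range(10):
            t_before = sim.next_event[0]
            sim.step_event()
            assert len(sim.next_t) == 4
            assert sim.next_event[0] >= t_before


class TestRunSimulation:
    def test_same_seed_bit_identical(self, small_params):
        a = run_simulation(small_params, 40, seed=9)
        b = run_simulation(small_params, 40, seed=9)
        for f in ("times", "positions", "headings", "speeds", "kick_index"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_backends_bit_identical(self, small_params):
        a = run_simulation(small_params, 60, seed=3, backend="numba",
                           log_kicks=True)
        b = run_simulation(small_params, 60, seed=3, backend="python",
                           log_kicks=True)
        for f in ("times", "positions", "headings", "speeds", "kick_index"):
            assert np.array_equal(getattr(a, f), getattr(b, f))
        assert (a.kick_log.values == b.kick_log.values).all()

    def test_snapshot_times_strictly_increasing(self, small_params):
        tr = run_simulation(small_params, 30, seed=2)
        assert np.all(np.diff(tr.times) > 0)

    def test_total_kick_events(self, small_params):
        tr = run_simulation(small_params, 30, seed=2)
        assert tr.n_events == small_params.n_fish * 30
        assert tr.kick_index[-1].sum() == tr.n_events

    def test_single_fish_random_walk_of_straight_kicks(self):
        # kick anchors are joined by straight glides of the sampled length
        p = ModelParams(gamma_att=0.0, gamma_ali=0.0, n_fish=1)
        tr = run_simulation(p, 50, seed=8, log_kicks=True,
                            snapshot_interval=0.25)
        taus = tr.kick_log["tau"].to_numpy()
        t_kicks = tr.kick_log["t_kick"].to_numpy()
        # positions sampled within one glide lie on a straight segment
        seg = (tr.times >= t_kicks[10]) & (tr.times <= t_kicks[10] + taus[10])
        pts = tr.positions[seg, 0, :]
        d = pts[-1] - pts[0]
        for q in pts[1:-1]:
            cross = (q - pts[0])[0] * d[1] - (q - pts[0])[1] * d[0]
            assert abs(cross) < 1e-9

    def test_attraction_only_pair_approaches(self):
        # two distant fish with pure attraction turn towards each other and
        # close in until they meet (after crossing, each sits in the
        # other's rear blind spot — sin(psi) ~ 0 — and the pull vanishes)
        p = ModelParams(gamma_att=0.6, gamma_ali=0.0, gamma_r=0.0, n_fish=2,
                        kick_sd=0.0)
        states = [FishState(0, np.array([-8.0, 0.0]), math.pi / 2, 0.0, 1.0,
                            next_kick_time=0.5),
                  FishState(1, np.array([8.0, 0.0]), -math.pi / 2, 0.0, 1.0)]
        sim = make_sim(states, p, seed=0)
        gaps = []
        for _ in range(60):
            sim.step_event()
            snap = sim.snapshot(sim.t)
            gaps.append(np.linalg.norm(snap.positions[0] - snap.positions[1]))
        assert all(a > b for a, b in zip(gaps[:16], gaps[1:17]))
        assert min(gaps) < 2.0

    def test_event_loop_matches_bruteforce_integrator(self):
        # independent fixed-timestep integrator that checks kick times
        # explicitly, N=3, deterministic conditions (no noise, fixed tau)
        p = ModelParams(gamma_att=0.5, gamma_ali=0.4, gamma_r=0.0, n_fish=3,
                        kick_sd=0.0)
        pos0 = np.array([[0.0, 0.0], [1.5, 0.5], [-0.5, 1.8]])
        head0 = np.array([0.3, 2.0, -1.2])
        first = np.array([0.25, 0.6, 0.85])
        states = [FishState(i, pos0[i].copy(), head0[i], 0.0, 1.0,
                            next_kick_time=first[i]) for i in range(3)]
        tr = run_simulation_from_states(p, states, n_kicks=10)

        oracle = BruteForceIntegrator(p, pos0, head0, first)
        for t, snap_pos in zip(tr.times, tr.positions):
            oracle.advance_to(t)
            assert np.allclose(snap_pos, oracle.positions_at(t), atol=1e-6)


def run_simulation_from_states(params, states, n_kicks):
    """Event-driven run from explicit states, recording every 0.5 units."""
    from burstschool.core import _run_python_backend, Trajectory

    out = _run_python_backend(params, states, kernel_seed=1,
                              n_target=params.n_fish * n_kicks, snap_dt=0.5,
                              log_kicks=False)
    return Trajectory(params=params, seed=1, times=out[0], positions=out[1],
                      headings=out[2], speeds=out[3], kick_index=out[4],
                      n_events=params.n_fish * n_kicks)


class BruteForceIntegrator:
    """Fixed-small-timestep integrator used as an independent oracle.

    Marches time in steps of 1e-3, explicitly checking each fish's pending
    kick time, and evaluates social turns via the angle-based pair law
    (relative_state + pair_interaction) rather than the engine's internals.
    All kicks have duration 1 and there is no noise, so the dynamics is
    deterministic.
    """

    DT = 1e-3

    def __init__(self, params, positions, headings, first_kicks):
        self.p = params
        self.pos = positions.astype(float).copy()
        self.head = headings.astype(float).copy()
        self.t_kick = np.zeros(len(headings))
        self.tau = np.ones(len(headings))
        self.next_kick = first_kicks.astype(float).copy()
        self.t = 0.0

    def _glide(self, i, t):
        s = min(max(t - self.t_kick[i], 0.0), self.tau[i])
        frac = (1 - math.exp(-s / self.p.tau0)) / (
            1 - math.exp(-self.tau[i] / self.p.tau0))
        e = np.array([math.cos(self.head[i]), math.sin(self.head[i])])
        return self.pos[i] + self.tau[i] * frac * e

    def positions_at(self, t):
        return np.array([self._glide(i, t) for i in range(len(self.head))])

    def _kick(self, i, t_event):
        cur = self.positions_at(t_event)
        contribs = []
        for j in range(len(self.head)):
            if j == i:
                continue
            rel = relative_state(cur[i], self.head[i], cur[j], self.head[j])
            contribs.append((j, pair_interaction(rel, self.p)))
        contribs.sort(key=lambda c: (-abs(c[1]), c[0]))
        social = sum(v for _, v in contribs[: self.p.k])
        self.pos[i] = cur[i]
        self.head[i] = self.head[i] + social
        self.t_kick[i] = t_event
        self.next_kick[i] = t_event + self.tau[i]

    def advance_to(self, t_target):
        while self.t < t_target:
            step_end = min(self.t + self.DT, t_target)
            while True:
                due = [i for i in range(len(self.head))
                       if self.next_kick[i] <= step_end]
                if not due:
                    break
                i = min(due, key=lambda i: (self.next_kick[i], i))
                self._kick(i, self.next_kick[i])
            self.t = step_end


class TestInitialConditions:
    def test_circle_radius_formula(self, rng):
        # R = (l_att/2) * sqrt(N/pi): typical spacing is half the range
        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=100, l_att=3.0)
        radius = 1.5 * math.sqrt(100 / math.pi)
        assert radius == pytest.approx(8.4628, abs=1e-4)
        states = init_circle(p, rng)
        r = np.array([np.linalg.norm(st.pos_kick) for st in states])
        assert (r <= radius + 1e-12).all()

    def test_circle_headings_uniform(self, rng):
        from scipy.stats import kstest

        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=20_000)
        states = init_circle(p, rng)
        h = np.array([st.heading for st in states])
        stat = kstest(h, "uniform", args=(-math.pi, 2 * math.pi))
        assert stat.pvalue > 1e-3

    def test_staggered_first_kicks_inside_first_interval(self, rng):
        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=200)
        states = init_circle(p, rng)
        for st in states:
            assert 0.0 <= st.next_kick_time < st.tau
        sync = init_circle(p, rng, stagger=False)
        for st in sync:
            assert st.next_kick_time == st.tau

    def test_ellipse_support_and_headings(self, rng):
        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=500)
        states = init_ellipse(p, 10.0, 4.0, rng)
        for st in states:
            x, y = st.pos_kick
            assert (x / 10.0) ** 2 + (y / 4.0) ** 2 <= 1.0 + 1e-12
            assert st.heading == 0.0

    def test_ellipse_equal_axes_is_disc(self, rng):
        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=500)
        states = init_ellipse(p, 5.0, 5.0, rng)
        r = np.array([np.linalg.norm(st.pos_kick) for st in states])
        assert (r <= 5.0 + 1e-12).all()

    def test_ellipse_rejects_invalid_axes(self, rng):
        p = ModelParams(gamma_att=0.1, gamma_ali=0.1, n_fish=5)
        with pytest.raises(ValueError):
            init_ellipse(p, 2.0, 3.0, rng)
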