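"""Event-driven dynamics of burst-and-coast agents.

Each fish moves in discrete "kicks": at a kick it instantaneously picks a
new heading and a new kick length/duration, then glides along a straight
line while its speed decays exponentially (relaxation time ``tau0``) until
its next kick.  Kicks of different fish are asynchronous, so the school is
simulated as a sequence of kick events ordered in time.  At its kick a fish
evaluates the heading change every other fish would induce (attraction +
alignment, dead-reckoned to the kick instant), keeps only the ``k`` most
influential neighbours, and adds their contributions plus Gaussian noise to
its heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .params import ModelParams

TWO_PI = 2.0 * math.pi


def wrap_angle(angle):
    """Wrap an angle (scalar or array, radians) to the interval (-pi, pi]."""
    return np.pi - (np.pi - np.asarray(angle)) % TWO_PI if np.ndim(angle) else math.pi - (math.pi - angle) % TWO_PI


def unit_vector(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


@dataclass
class FishState:
    """Kick-anchored kinematic state of one fish.

    ``pos_kick`` and ``heading`` describe the glide segment that started at
    time ``t_kick`` and lasts ``tau`` time units; the kick length equals
    ``tau`` (unit speed scale).  ``next_kick_time`` is normally
    ``t_kick + tau`` but may be earlier for the staggered first kick of a
    run, in which case the first glide segment is simply interrupted.
    """

    id: int
    pos_kick: np.ndarray
    heading: float
    t_kick: float
    tau: float
    next_kick_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.pos_kick = np.asarray(self.pos_kick, dtype=float)
        if self.tau <= 0:
            raise ValueError(f"kick duration must be > 0, got {self.tau}")
        self.heading = wrap_angle(float(self.heading))
        if self.next_kick_time is None:
            self.next_kick_time = self.t_kick + self.tau

    @property
    def length(self) -> float:
        """Kick length; equal to the duration (unit speed scale)."""
        return self.tau


@dataclass
class RelativeState:
    """State of a neighbour as perceived by a focal fish.

    ``psi`` is the viewing angle of the neighbour (angle of the focal-to-
    neighbour vector minus the focal heading) and ``phi_diff`` the heading
    difference; both wrapped to (-pi, pi].  ``psi`` is not symmetric under
    exchanging the two fish.
    """

    d: float
    psi: float
    phi_diff: float
    theta: float
    coincident: bool = False


@dataclass
class SchoolSnapshot:
    """Positions/headings/speeds of all fish at one wall-clock time."""

    time: float
    positions: np.ndarray   # (N, 2)
    headings: np.ndarray    # (N,)
    speeds: np.ndarray      # (N,)
    kick_index: Optional[np.ndarray] = None

    @property
    def n_fish(self) -> int:
        return len(self.headings)

    @property
    def velocities(self) -> np.ndarray:
        e = np.column_stack([np.cos(self.headings), np.sin(self.headings)])
        return self.speeds[:, None] * e


def sample_kick(rng, params: ModelParams, size: Optional[int] = None):
    """Sample kick duration and length from the truncated Gaussian.

    Returns a ``(tau, length)`` pair (equal by the unit speed scale); with
    ``size`` given, two identical arrays.  ``rng`` may be a Generator or a
    RandomState.
    """
    lo, hi = params.kick_min, params.kick_max
    if size is None:
        while True:
            x = rng.normal(params.kick_mean, params.kick_sd)
            if lo <= x <= hi:
                return float(x), float(x)
    out = np.empty(size)
    n_ok = 0
    while n_ok < size:
        draw = rng.normal(params.kick_mean, params.kick_sd, size=size - n_ok)
        good = draw[(draw >= lo) & (draw <= hi)]
        out[n_ok:n_ok + len(good)] = good
        n_ok += len(good)
    return out, out.copy()


def _glide_fraction(s, tau, tau0):
    """Fraction of the kick length covered after elapsed glide time s."""
    return (1.0 - np.exp(-np.asarray(s) / tau0)) / (1.0 - np.exp(-np.asarray(tau) / tau0))


def _check_elapsed(s: float, tau: float) -> float:
    if s < -1e-12 or s > tau * (1.0 + 1e-12):
        raise ValueError(f"elapsed time {s} outside glide interval [0, {tau}]")
    return min(max(s, 0.0), tau)


def glide_position(state: FishState, s: float, params: ModelParams) -> np.ndarray:
    """Position of a gliding fish, s time units after its kick onset.

    The speed decays exponentially with relaxation time ``tau0``, so the
    covered fraction of the kick length is
    ``(1 - exp(-s/tau0)) / (1 - exp(-tau/tau0))``.
    """
    s = _check_elapsed(s, state.tau)
    frac = _glide_fraction(s, state.tau, params.tau0)
    return state.pos_kick + (state.tau * frac) * unit_vector(state.heading)


def instantaneous_speed(state: FishState, s: float, params: ModelParams) -> float:
    """Instantaneous glide speed, s time units after kick onset.

    Time derivative of the glide displacement: integrates to the kick
    length over [0, tau] and decays exponentially in between.
    """
    s = _check_elapsed(s, state.tau)
    tau0 = params.tau0
    return (state.tau / tau0) * math.exp(-s / tau0) / (1.0 - math.exp(-state.tau / tau0))


def relative_state(focal_pos, focal_heading, nbr_pos, nbr_heading) -> RelativeState:
    """Relative state (d, psi, phi_diff) of a neighbour seen by a focal fish."""
    focal_pos = np.asarray(focal_pos, dtype=float)
    nbr_pos = np.asarray(nbr_pos, dtype=float)
    dx, dy = nbr_pos - focal_pos
    d = math.sqrt(dx * dx + dy * dy)
    coincident = d == 0.0
    theta = 0.0 if coincident else math.atan2(dy, dx)
    return RelativeState(
        d=d,
        psi=wrap_angle(theta - focal_heading),
        phi_diff=wrap_angle(nbr_heading - focal_heading),
        theta=theta,
        coincident=coincident,
    )


def pair_interaction(rel: RelativeState, params: ModelParams) -> float:
    """Heading change a neighbour induces: attraction + alignment.

    Attraction is odd in the viewing angle psi (neighbours on the right
    turn the fish right), grows linearly at short range and decays beyond
    ``l_att``.  Alignment is odd in the heading difference, Gaussian in
    distance with range ``l_ali``, and stronger for neighbours ahead
    (anisotropy ``epsilon``).
    """
    d, psi, phid = rel.d, rel.psi, rel.phi_diff
    att = params.gamma_att * d * math.sin(psi) / (1.0 + (d / params.l_att) ** 2)
    ali = (
        params.gamma_ali
        * (1.0 + params.epsilon * math.cos(psi))
        * math.exp(-((d / params.l_ali) ** 2))
        * math.sin(phid)
    )
    return att + ali


def _pairwise_dphi(focal_idx, positions, headings, params):
    """Vectorised heading-change contributions of every other fish."""
    delta = positions - positions[focal_idx]
    dx, dy = delta[:, 0], delta[:, 1]
    d = np.sqrt(dx * dx + dy * dy)
    theta = np.arctan2(dy, dx)   # atan2(0,0) = 0: coincident convention
    psi = wrap_angle(theta - headings[focal_idx])
    phid = wrap_angle(headings - headings[focal_idx])
    att = params.gamma_att * d * np.sin(psi) / (1.0 + (d / params.l_att) ** 2)
    ali = (
        params.gamma_ali
        * (1.0 + params.epsilon * np.cos(psi))
        * np.exp(-((d / params.l_ali) ** 2))
        * np.sin(phid)
    )
    return att + ali


def select_influential(focal: FishState, snapshot_at_kick: SchoolSnapshot,
                       params: ModelParams) -> list[tuple[int, float]]:
    """Pick the <= k neighbours with the largest |heading change| influence.

    ``snapshot_at_kick`` must hold every fish dead-reckoned to the focal
    fish's kick instant.  Influence is the magnitude of the heading change
    a neighbour would induce; ties are broken by ascending fish id.
    """
    n = snapshot_at_kick.n_fish
    if n <= 1:
        return []
    dphi = _pairwise_dphi(focal.id, snapshot_at_kick.positions,
                          snapshot_at_kick.headings, params)
    ids = np.arange(n)
    mask = ids != focal.id
    ids, dphi = ids[mask], dphi[mask]
    order = np.lexsort((ids, -np.abs(dphi)))
    top = order[: params.k]
    return [(int(ids[j]), float(dphi[j])) for j in top]


def kick_update(focal: FishState, influentials: Sequence[tuple[int, float]],
                rng, params: ModelParams, t_event: Optional[float] = None) -> FishState:
    """Perform the focal fish's kick: move to the glide end, turn, resample.

    The new heading adds Gaussian noise (scaled by ``gamma_r``) and the
    summed contributions of the influential neighbours to the old heading.
    """
    if t_event is None:
        t_event = focal.next_kick_time
    s = t_event - focal.t_kick
    new_pos = glide_position(focal, s, params)
    g = rng.normal(params.noise_mean, 1.0)
    noise = params.gamma_r * g
    social = 0.0
    for _, dphi in influentials:
        social += dphi
    new_heading = wrap_angle(focal.heading + noise + social)
    tau, _ = sample_kick(rng, params)
    return FishState(focal.id, new_pos, new_heading, t_event, tau)


# ---------------------------------------------------------------------------
# initial conditions

def init_circle(params: ModelParams, rng, stagger: bool = True) -> list[FishState]:
    """Fish uniformly placed in a disc with uniform random headings.

    The disc radius ``R = (l_att / 2) * sqrt(N / pi)`` makes the typical
    inter-fish distance ``sqrt(pi R^2 / N)`` equal to half the attraction
    range.  With ``stagger`` (default), each fish's first kick event is
    drawn uniformly inside its first kick interval so kicks desynchronise
    immediately; the first glide segment is interrupted at that instant.
    """
    n = params.n_fish
    radius = 0.5 * params.l_att * math.sqrt(n / math.pi)
    r = radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(-math.pi, math.pi, size=n)
    positions = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    headings = rng.uniform(-math.pi, math.pi, size=n)
    taus, _ = sample_kick(rng, params, size=n)
    first = rng.uniform(size=n) * taus if stagger else taus.copy()
    return [
        FishState(i, positions[i], headings[i], 0.0, taus[i], next_kick_time=first[i])
        for i in range(n)
    ]


def init_ellipse(params: ModelParams, a: float, b: float, rng,
                 stagger: bool = True) -> list[FishState]:
    """Fish uniformly placed in an ellipse, all heading along +x.

    ``a`` and ``b`` are the long and short half-axes (long axis along x);
    requires ``a >= b > 0``.
    """
    if not (a >= b > 0):
        raise ValueError(f"ellipse half-axes must satisfy a >= b > 0, got a={a}, b={b}")
    n = params.n_fish
    r = np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(-math.pi, math.pi, size=n)
    positions = np.column_stack([a * r * np.cos(ang), b * r * np.sin(ang)])
    taus, _ = sample_kick(rng, params, size=n)
    first = rng.uniform(size=n) * taus if stagger else taus.copy()
    return [
        FishState(i, positions[i], 0.0, 0.0, taus[i], next_kick_time=first[i])
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# event engine (reference implementation; the numba kernel mirrors it)

class Simulation:
    """Asynchronous event loop over kick events, one fish at a time.

    This is the readable reference engine; :func:`run_simulation` uses the
    compiled kernel by default, which mirrors this class operation for
    operation (bit-identical output for a given seed).  The event "queue"
    is the per-fish array of next kick times: the next event is its
    minimum, ties resolved by ascending fish id.

    The social terms are evaluated through exact trigonometric identities
    (cross/dot products with the focal heading vector) rather than through
    the angles psi and phi_diff themselves; :func:`pair_interaction` is the
    angle-based form of the same law.
    """

    def __init__(self, params: ModelParams, states: Sequence[FishState], seed: int):
        self.params = params
        n = len(states)
        if n != params.n_fish:
            raise ValueError(f"got {n} fish states for n_fish={params.n_fish}")
        self.pos_kick = np.array([st.pos_kick for st in states], dtype=float)
        self.heading = np.array([st.heading for st in states], dtype=float)
        self.t_kick = np.array([st.t_kick for st in states], dtype=float)
        self.tau = np.array([st.tau for st in states], dtype=float)
        self.next_t = np.array([st.next_kick_time for st in states], dtype=float)
        self.kick_count = np.zeros(n, dtype=np.int64)
        self.rng = np.random.RandomState(seed)
        self.t = 0.0
        self.n_events = 0

    @property
    def n_fish(self) -> int:
        return len(self.heading)

    @property
    def next_event(self) -> tuple[float, int]:
        n = self.n_fish
        i = 0
        t = self.next_t[0]
        for j in range(1, n):
            if self.next_t[j] < t:
                t = self.next_t[j]
                i = j
        return float(t), i

    def state_of(self, i: int) -> FishState:
        return FishState(i, self.pos_kick[i].copy(), float(self.heading[i]),
                         float(self.t_kick[i]), float(self.tau[i]),
                         next_kick_time=float(self.next_t[i]))

    def _dead_reckon_fish(self, j: int, t: float) -> tuple[float, float]:
        tau0 = self.params.tau0
        s = t - self.t_kick[j]
        es = math.exp(-s / tau0)
        denom = 1.0 - math.exp(-self.tau[j] / tau0)
        adv = self.tau[j] * ((1.0 - es) / denom)
        return (self.pos_kick[j, 0] + adv * math.cos(self.heading[j]),
                self.pos_kick[j, 1] + adv * math.sin(self.heading[j]))

    def snapshot(self, t: Optional[float] = None) -> SchoolSnapshot:
        """School state at time t (default: time of the last event).

        Valid for t between the last processed event and the next one, so
        that no fish has passed its own next kick.
        """
        if t is None:
            t = self.t
        n = self.n_fish
        tau0 = self.params.tau0
        pos = np.empty((n, 2))
        speeds = np.empty(n)
        for j in range(n):
            pos[j] = self._dead_reckon_fish(j, t)
            s = t - self.t_kick[j]
            es = math.exp(-s / tau0)
            denom = 1.0 - math.exp(-self.tau[j] / tau0)
            speeds[j] = (self.tau[j] / tau0) * es / denom
        return SchoolSnapshot(time=t, positions=pos, headings=self.heading.copy(),
                              speeds=speeds, kick_index=self.kick_count.copy())

    def step_event(self) -> dict:
        """Process the earliest pending kick event and return its record."""
        p = self.params
        n = self.n_fish
        t, i = self.next_event
        cur = [self._dead_reckon_fish(j, t) for j in range(n)]
        ci = math.cos(self.heading[i])
        si = math.sin(self.heading[i])
        best1 = best2 = -1
        v1 = v2 = -1.0
        dphi = np.zeros(n)
        for j in range(n):
            if j == i:
                continue
            dx = cur[j][0] - cur[i][0]
            dy = cur[j][1] - cur[i][1]
            d = math.sqrt(dx * dx + dy * dy)
            # d*sin(psi) = dy*cos(phi_i) - dx*sin(phi_i); d*cos(psi) = dx*ci + dy*si
            if d > 0.0:
                q = d / p.l_att
                att = p.gamma_att * (dy * ci - dx * si) / (1.0 + q * q)
                cpsi = (dx * ci + dy * si) / d
            else:
                att = 0.0
                cpsi = ci  # coincident: theta := 0, so cos(psi) = cos(-phi_i)
            w = d / p.l_ali
            sphid = math.sin(self.heading[j]) * ci - math.cos(self.heading[j]) * si
            ali = p.gamma_ali * (1.0 + p.epsilon * cpsi) * math.exp(-(w * w)) * sphid
            val = att + ali
            dphi[j] = val
            a = abs(val)
            if a > v1:
                best2, v2 = best1, v1
                best1, v1 = j, a
            elif a > v2:
                best2, v2 = j, a
        social = 0.0
        infl_ids = []
        if best1 >= 0:
            social += dphi[best1]
            infl_ids.append(best1)
        if p.k == 2 and best2 >= 0:
            social += dphi[best2]
            infl_ids.append(best2)
        g = self.rng.normal(p.noise_mean, 1.0)
        noise = p.gamma_r * g
        new_tau, _ = sample_kick(self.rng, p)
        self.pos_kick[i] = cur[i]
        self.heading[i] = wrap_angle(float(self.heading[i]) + noise + social)
        self.t_kick[i] = t
        self.tau[i] = new_tau
        self.next_t[i] = t + new_tau
        self.kick_count[i] += 1
        self.t = t
        self.n_events += 1
        return {"t_kick": t, "fish_id": i, "tau": new_tau,
                "delta_phi_social": social, "delta_phi_noise": noise,
                "influential_ids": infl_ids}


# ---------------------------------------------------------------------------
# full runs

@dataclass
class Trajectory:
    """Snapshots of a run at a fixed sampling interval, plus metadata."""

    params: ModelParams
    seed: int
    times: np.ndarray        # (T,)
    positions: np.ndarray    # (T, N, 2)
    headings: np.ndarray     # (T, N)
    speeds: np.ndarray       # (T, N)
    kick_index: np.ndarray   # (T, N)
    n_events: int
    kick_log: Optional["pd.DataFrame"] = field(default=None, repr=False)

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def snapshot(self, i: int) -> SchoolSnapshot:
        return SchoolSnapshot(time=float(self.times[i]), positions=self.positions[i],
                              headings=self.headings[i], speeds=self.speeds[i],
                              kick_index=self.kick_index[i])

    def __iter__(self) -> Iterator[SchoolSnapshot]:
        return (self.snapshot(i) for i in range(self.n_snapshots))

    def to_dataframe(self):
        """Long-format trajectory table: time, fish_id, x, y, heading, speed, kick_index."""
        import pandas as pd

        t_len, n = self.headings.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, n),
            "fish_id": np.tile(np.arange(n), t_len),
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "heading": self.headings.ravel(),
            "speed": self.speeds.ravel(),
            "kick_index": self.kick_index.ravel(),
        })

    def order_parameters(self):
        from .observables import order_parameters

        return order_parameters(self)


def _derive_seeds(seed: int) -> tuple[np.random.Generator, int]:
    """Split a master seed into an init stream and a 31-bit kernel seed."""
    ss = np.random.SeedSequence(seed)
    init_ss, kern_ss = ss.spawn(2)
    kernel_seed = int(kern_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return np.random.default_rng(init_ss), kernel_seed


def run_simulation(params: ModelParams, kicks_per_fish: int, seed: int,
                   init: str = "circle", a: Optional[float] = None,
                   b: Optional[float] = None, snapshot_interval: float = 1.0,
                   backend: str = "numba", log_kicks: bool = False,
                   stagger: bool = True) -> Trajectory:
    """Run the school until N * kicks_per_fish kick events have occurred.

    Snapshots are recorded at multiples of ``snapshot_interval`` plus one
    final snapshot at the last event time.  Given the same seed the output
    is bit-identical, for either backend ("numba" or "python", which agree
    exactly).
    """
    init_rng, kernel_seed = _derive_seeds(seed)
    if init == "circle":
        states = init_circle(params, init_rng, stagger=stagger)
    elif init == "ellipse":
        if a is None or b is None:
            raise ValueError("ellipse init requires half-axes a and b")
        states = init_ellipse(params, a, b, init_rng, stagger=stagger)
    else:
        raise ValueError(f"unknown init mode {init!r}")
    n_target = params.n_fish * kicks_per_fish
    if backend == "numba":
        out = _run_kernel_backend(params, states, kernel_seed, n_target,
                                  snapshot_interval, log_kicks)
    elif backend == "python":
        out = _run_python_backend(params, states, kernel_seed, n_target,
                                  snapshot_interval, log_kicks)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    times, positions, headings, speeds, kick_index, log = out
    return Trajectory(params=params, seed=seed, times=times, positions=positions,
                      headings=headings, speeds=speeds, kick_index=kick_index,
                      n_events=n_target, kick_log=log)


def _log_to_frame(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["t_kick", "fish_id", "tau",
                                       "delta_phi_social", "delta_phi_noise",
                                       "influential_ids"])


def _run_python_backend(params, states, kernel_seed, n_target, snap_dt, log_kicks):
    sim = Simulation(params, states, seed=kernel_seed)
    snap_times, snap_pos, snap_head, snap_speed, snap_kidx = [], [], [], [], []
    rows = [] if log_kicks else None

    def record(t):
        s = sim.snapshot(t)
        snap_times.append(t)
        snap_pos.append(s.positions)
        snap_head.append(s.headings)
        snap_speed.append(s.speeds)
        snap_kidx.append(s.kick_index)

    next_snap = 0.0
    t_last = 0.0
    while sim.n_events < n_target:
        t_event, _ = sim.next_event
        while next_snap <= t_event:
            record(next_snap)
            next_snap += snap_dt
        info = sim.step_event()
        t_last = info["t_kick"]
        if log_kicks:
            rows.append((info["t_kick"], info["fish_id"], info["tau"],
                         info["delta_phi_social"], info["delta_phi_noise"],
                         ";".join(str(j) for j in info["influential_ids"])))
    if snap_times and snap_times[-1] == t_last:
        for arr in (snap_times, snap_pos, snap_head, snap_speed, snap_kidx):
            arr.pop()
    record(t_last)
    return (np.array(snap_times), np.array(snap_pos), np.array(snap_head),
            np.array(snap_speed), np.array(snap_kidx),
            _log_to_frame(rows) if log_kicks else None)


def _run_kernel_backend(params, states, kernel_seed, n_target, snap_dt, log_kicks):
    from ._kernel import run_events

    p = params
    pos0 = np.array([st.pos_kick for st in states], dtype=float)
    head0 = np.array([st.heading for st in states], dtype=float)
    tkick0 = np.array([st.t_kick for st in states], dtype=float)
    tau0 = np.array([st.tau for st in states], dtype=float)
    next0 = np.array([st.next_kick_time for st in states], dtype=float)
    max_snaps = int(1.5 * n_target * p.kick_mean / (p.n_fish * snap_dt)) + 64
    out = run_events(pos0, head0, tkick0, tau0, next0, kernel_seed, n_target,
                     p.gamma_att, p.gamma_ali, p.l_att, p.l_ali, p.epsilon,
                     p.gamma_r, p.tau0, p.k, p.kick_mean, p.kick_sd,
                     p.kick_min, p.kick_max, p.noise_mean, snap_dt, max_snaps,
                     log_kicks)
    (n_snaps, s_times, s_pos, s_head, s_speed, s_kidx,
     log_t, log_id, log_tau, log_soc, log_noise, log_j1, log_j2) = out
    if n_snaps >= max_snaps:
        raise RuntimeError("snapshot buffer overflow; kick durations far above mean")
    log = None
    if log_kicks:
        ids = [";".join(str(j) for j in (a, b) if j >= 0)
               for a, b in zip(log_j1, log_j2)]
        log = _log_to_frame(list(zip(log_t, log_id, log_tau, log_soc, log_noise, ids)))
    return (s_times[:n_snaps], s_pos[:n_snaps], s_head[:n_snaps],
            s_speed[:n_snaps], s_kidx[:n_snaps], log)
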