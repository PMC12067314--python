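"""Compiled event loop.

Mirrors :class:`burstschool.core.Simulation` operation for operation (same
arithmetic ordering, same random draw order) so that for a given seed the
two backends produce bit-identical trajectories.  Numba's ``np.random``
reproduces NumPy's legacy ``RandomState`` sequences, which the Python
engine uses.  Per-fish heading cosine/sine and the glide-denominator
``1 - exp(-tau/tau0)`` only change at that fish's kicks and are cached.
"""

import numpy as np
from numba import njit

PI = np.pi
TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(x):
    return PI - (PI - x) % TWO_PI


@njit(cache=True)
def run_events(pos0, head0, tkick0, tau_arr0, next0, seed, n_target,
               g_att, g_ali, l_att, l_ali, eps, g_r, tau0, k,
               kick_mean, kick_sd, kick_min, kick_max, noise_mean,
               snap_dt, max_snaps, log_kicks):
    np.random.seed(seed)
    n = head0.shape[0]
    pos = pos0.copy()
    heading = head0.copy()
    t_kick = tkick0.copy()
    tau = tau_arr0.copy()
    next_t = next0.copy()
    kick_count = np.zeros(n, dtype=np.int64)

    ch = np.cos(heading)
    sh = np.sin(heading)
    denom = 1.0 - np.exp(-tau / tau0)

    s_times = np.zeros(max_snaps)
    s_pos = np.zeros((max_snaps, n, 2))
    s_head = np.zeros((max_snaps, n))
    s_speed = np.zeros((max_snaps, n))
    s_kidx = np.zeros((max_snaps, n), dtype=np.int64)
    n_snaps = 0

    n_log = n_target if log_kicks else 0
    log_t = np.zeros(n_log)
    log_id = np.zeros(n_log, dtype=np.int64)
    log_tau = np.zeros(n_log)
    log_soc = np.zeros(n_log)
    log_noise = np.zeros(n_log)
    log_j1 = np.full(n_log, -1, dtype=np.int64)
    log_j2 = np.full(n_log, -1, dtype=np.int64)

    cur = np.zeros((n, 2))
    dphi = np.zeros(n)
    next_snap = 0.0
    t_last = 0.0
    n_events = 0
    while n_events < n_target:
        # next event: earliest pending kick, lowest id on ties
        i = 0
        t = next_t[0]
        for j in range(1, n):
            if next_t[j] < t:
                t = next_t[j]
                i = j
        # snapshots due before (or at) this event reflect the pre-kick state
        while next_snap <= t and n_snaps < max_snaps:
            s_times[n_snaps] = next_snap
            for j in range(n):
                s = next_snap - t_kick[j]
                es = np.exp(-s / tau0)
                adv = tau[j] * ((1.0 - es) / denom[j])
                s_pos[n_snaps, j, 0] = pos[j, 0] + adv * ch[j]
                s_pos[n_snaps, j, 1] = pos[j, 1] + adv * sh[j]
                s_head[n_snaps, j] = heading[j]
                s_speed[n_snaps, j] = (tau[j] / tau0) * es / denom[j]
                s_kidx[n_snaps, j] = kick_count[j]
            n_snaps += 1
            next_snap += snap_dt

        # dead-reckon every fish to the kick instant
        for j in range(n):
            s = t - t_kick[j]
            es = np.exp(-s / tau0)
            adv = tau[j] * ((1.0 - es) / denom[j])
            cur[j, 0] = pos[j, 0] + adv * ch[j]
            cur[j, 1] = pos[j, 1] + adv * sh[j]

        # influence of every neighbour; keep the top k (low id wins ties)
        ci = ch[i]
        si = sh[i]
        best1 = -1
        best2 = -1
        v1 = -1.0
        v2 = -1.0
        for j in range(n):
            if j == i:
                continue
            dx = cur[j, 0] - cur[i, 0]
            dy = cur[j, 1] - cur[i, 1]
            d = np.sqrt(dx * dx + dy * dy)
            # d*sin(psi) = dy*ci - dx*si ; d*cos(psi) = dx*ci + dy*si
            if d > 0.0:
                q = d / l_att
                att = g_att * (dy * ci - dx * si) / (1.0 + q * q)
                cpsi = (dx * ci + dy * si) / d
            else:
                att = 0.0
                cpsi = ci  # coincident: theta := 0, so cos(psi) = cos(-phi_i)
            w = d / l_ali
            sphid = sh[j] * ci - ch[j] * si
            ali = g_ali * (1.0 + eps * cpsi) * np.exp(-(w * w)) * sphid
            val = att + ali
            dphi[j] = val
            a = abs(val)
            if a > v1:
                best2 = best1
                v2 = v1
                best1 = j
                v1 = a
            elif a > v2:
                best2 = j
                v2 = a
        social = 0.0
        if best1 >= 0:
            social += dphi[best1]
        if k == 2 and best2 >= 0:
            social += dphi[best2]

        g = np.random.normal(noise_mean, 1.0)
        noise = g_r * g
        while True:
            new_tau = np.random.normal(kick_mean, kick_sd)
            if kick_min <= new_tau <= kick_max:
                break

        pos[i, 0] = cur[i, 0]
        pos[i, 1] = cur[i, 1]
        heading[i] = _wrap(heading[i] + noise + social)
        ch[i] = np.cos(heading[i])
        sh[i] = np.sin(heading[i])
        t_kick[i] = t
        tau[i] = new_tau
        denom[i] = 1.0 - np.exp(-new_tau / tau0)
        next_t[i] = t + new_tau
        kick_count[i] += 1
        if log_kicks:
            log_t[n_events] = t
            log_id[n_events] = i
            log_tau[n_events] = new_tau
            log_soc[n_events] = social
            log_noise[n_events] = noise
            log_j1[n_events] = best1
            if k == 2:
                log_j2[n_events] = best2
        t_last = t
        n_events += 1

    # final snapshot at the last event time (replacing an exact duplicate)
    if n_snaps > 0 and s_times[n_snaps - 1] == t_last:
        n_snaps -= 1
    if n_snaps < max_snaps:
        s_times[n_snaps] = t_last
        for j in range(n):
            s = t_last - t_kick[j]
            es = np.exp(-s / tau0)
            adv = tau[j] * ((1.0 - es) / denom[j])
            s_pos[n_snaps, j, 0] = pos[j, 0] + adv * ch[j]
            s_pos[n_snaps, j, 1] = pos[j, 1] + adv * sh[j]
            s_head[n_snaps, j] = heading[j]
            s_speed[n_snaps, j] = (tau[j] / tau0) * es / denom[j]
            s_kidx[n_snaps, j] = kick_count[j]
        n_snaps += 1

    return (n_snaps, s_times, s_pos, s_head, s_speed, s_kidx,
            log_t, log_id, log_tau, log_soc, log_noise, log_j1, log_j2)
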