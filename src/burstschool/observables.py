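"""Order parameters of the school: dispersion, polarization, milling.

Dispersion D is the mean squared distance of fish to the group barycentre;
polarization P is the norm of the mean heading unit vector (1 for a fully
aligned school, of order 1/sqrt(N) for uncorrelated headings); the milling
index M is the absolute mean of sin(phibar - thetabar) in the barycentre
frame, close to 1 when the school turns coherently around its barycentre
in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SchoolSnapshot, Trajectory

#: below this barycentre-frame radius or speed a fish has no defined
#: position/velocity angle and is left out of the milling average
DEGENERACY_TOL = 1e-12


@dataclass
class OrderRecord:
    """Time-stamped order parameters, optionally with group statistics."""

    time: float
    dispersion: float
    polarization: float
    milling: float
    barycentre_pos: np.ndarray
    barycentre_vel: np.ndarray
    n_groups: int | None = None
    largest_group: int | None = None
    group_dispersion: float | None = None


def barycentre(snapshot: SchoolSnapshot) -> tuple[np.ndarray, np.ndarray]:
    """Mean position and mean velocity of the school."""
    return (snapshot.positions.mean(axis=0), snapshot.velocities.mean(axis=0))


def dispersion(snapshot: SchoolSnapshot) -> float:
    """Mean squared distance to the barycentre."""
    rel = snapshot.positions - snapshot.positions.mean(axis=0)
    return float(np.mean(np.sum(rel * rel, axis=1)))


def polarization(snapshot: SchoolSnapshot) -> float:
    """Norm of the mean heading unit vector; speed plays no role."""
    z = np.exp(1j * snapshot.headings)
    return float(np.abs(z.mean()))


def milling_index(snapshot: SchoolSnapshot) -> float:
    """Absolute mean of sin(phibar - thetabar) over the school.

    phibar and thetabar are the velocity and position angles in the
    barycentre frame (positions relative to the mean position, velocities
    relative to the mean velocity — note phibar is not the heading minus
    the barycentre heading).  sin(phibar - thetabar) equals the cross
    product of the barycentre-frame unit position and unit velocity, which
    avoids evaluating the angles.  Fish at the barycentre or with a
    vanishing barycentre-frame velocity have no defined angle and are
    excluded; if all fish are degenerate the index is 0.
    """
    rel_x = snapshot.positions - snapshot.positions.mean(axis=0)
    vel = snapshot.velocities
    rel_v = vel - vel.mean(axis=0)
    rn = np.sqrt(np.sum(rel_x * rel_x, axis=1))
    vn = np.sqrt(np.sum(rel_v * rel_v, axis=1))
    valid = (rn > DEGENERACY_TOL) & (vn > DEGENERACY_TOL)
    if not np.any(valid):
        return 0.0
    cross = rel_x[valid, 0] * rel_v[valid, 1] - rel_x[valid, 1] * rel_v[valid, 0]
    return float(abs(np.mean(cross / (rn[valid] * vn[valid]))))


def order_record(snapshot: SchoolSnapshot) -> OrderRecord:
    pos_b, vel_b = barycentre(snapshot)
    return OrderRecord(time=snapshot.time, dispersion=dispersion(snapshot),
                       polarization=polarization(snapshot),
                       milling=milling_index(snapshot),
                       barycentre_pos=pos_b, barycentre_vel=vel_b)


def order_parameters(trajectory: Trajectory):
    """P, M, D time series of a trajectory as a DataFrame (vectorised)."""
    import pandas as pd

    pos = trajectory.positions          # (T, N, 2)
    head = trajectory.headings
    spd = trajectory.speeds
    rel_x = pos - pos.mean(axis=1, keepdims=True)
    d_series = np.mean(np.sum(rel_x * rel_x, axis=2), axis=1)
    p_series = np.abs(np.mean(np.exp(1j * head), axis=1))

    vel = spd[:, :, None] * np.stack([np.cos(head), np.sin(head)], axis=2)
    rel_v = vel - vel.mean(axis=1, keepdims=True)
    rn = np.sqrt(np.sum(rel_x * rel_x, axis=2))
    vn = np.sqrt(np.sum(rel_v * rel_v, axis=2))
    valid = (rn > DEGENERACY_TOL) & (vn > DEGENERACY_TOL)
    cross = rel_x[:, :, 0] * rel_v[:, :, 1] - rel_x[:, :, 1] * rel_v[:, :, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_w = np.where(valid, cross / np.where(valid, rn * vn, 1.0), 0.0)
    n_valid = valid.sum(axis=1)
    m_series = np.where(
        n_valid > 0,
        np.abs(sin_w.sum(axis=1) / np.maximum(n_valid, 1)),
        0.0,
    )
    return pd.DataFrame({"time": trajectory.times, "P": p_series,
                         "M": m_series, "D": d_series})


def steady_state_mean(values, discard_fraction: float = 0.5) -> float:
    """Mean of a time series after discarding the initial transient.

    The leading ``discard_fraction`` of the samples (default: the first
    half) is dropped so that averages describe the steady state rather
    than the initial condition.
    """
    values = np.asarray(values, dtype=float)
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    start = int(np.floor(len(values) * discard_fraction))
    return float(values[start:].mean())


def retained_half(values, discard_fraction: float = 0.5) -> np.ndarray:
    """The post-transient part of a time series (see steady_state_mean)."""
    values = np.asarray(values)
    start = int(np.floor(len(values) * discard_fraction))
    return values[start:]
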