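"""Minimal plotting helpers for phase grids and trajectories."""

from __future__ import annotations

import numpy as np

PHASE_COLOURS = {"schooling": "tab:red", "milling": "tab:blue",
                 "swarming": "tab:green", "bistable": "tab:cyan",
                 "dispersal": "0.6"}


def plot_phase_grid(grid, quantity: str = "mean_P", ax=None, smooth_sigma=None):
    """Level plot of one averaged observable over the (att, ali) grid.

    ``smooth_sigma`` applies an optional Gaussian blur for presentation
    only; the stored grid data are never smoothed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = getattr(grid, quantity).T
    if smooth_sigma:
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(data, smooth_sigma)
    mesh = ax.pcolormesh(grid.gamma_att_axis, grid.gamma_ali_axis, data,
                         shading="nearest")
    ax.set_xlabel(r"attraction strength $\gamma_{Att}$")
    ax.set_ylabel(r"alignment strength $\gamma_{Ali}$")
    plt.colorbar(mesh, ax=ax, label=quantity)
    return ax


def plot_trajectory(trajectory, ax=None, max_fish: int = 20):
    """Spatial paths of (up to) the first ``max_fish`` fish."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = min(trajectory.positions.shape[1], max_fish)
    for i in range(n):
        ax.plot(trajectory.positions[:, i, 0], trajectory.positions[:, i, 1],
                lw=0.6)
    ax.set_aspect("equal")
    ax.set_xlabel("x (kick lengths)")
    ax.set_ylabel("y (kick lengths)")
    return ax
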