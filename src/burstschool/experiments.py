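"""Experiment batteries: phase diagrams, transect PDFs, long-run stability.

Collective phases are labelled from time-averaged order parameters (first
half of every run discarded as transient):

* schooling — P >= 0.4 and M < 0.3
* milling   — P < 0.4 and M >= 0.3
* swarming  — P < 0.4 and M < 0.3
* bistable  — P >= 0.4 and M >= 0.3 (school alternates schooling/milling)
* dispersal — D > 200 (the group has lost cohesion; not a collective phase)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import run_simulation
from .grouping import group_snapshot
from .observables import order_parameters, retained_half
from .params import ModelParams

P_SCHOOLING = 0.4    #: polarization threshold for the schooling phase
M_MILLING = 0.3      #: milling-index threshold for the milling phase
D_COHESION = 200.0   #: dispersion above which the group counts as dispersed

PHASES = ("schooling", "milling", "swarming", "bistable", "dispersal")

#: reference (gamma_att, gamma_ali) phase points used in the long-run
#: stability analysis, per interaction strategy k
REFERENCE_POINTS = {
    1: {"swarming": (0.6, 0.6), "schooling": (0.22, 0.6), "milling": (0.37, 0.2)},
    2: {"swarming": (0.6, 0.2), "schooling": (0.2, 0.3)},
}


def classify_phase(mean_p: float, mean_m: float, mean_d: float) -> str:
    """Phase label from time-averaged polarization, milling and dispersion."""
    if mean_d > D_COHESION:
        return "dispersal"
    if mean_p >= P_SCHOOLING and mean_m >= M_MILLING:
        return "bistable"
    if mean_p >= P_SCHOOLING:
        return "schooling"
    if mean_m >= M_MILLING:
        return "milling"
    return "swarming"


def _point_seed(master_seed: int, *indices: int) -> int:
    """Stable 31-bit seed for one (pixel, run) of a sweep."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_point(params: ModelParams, kicks_per_fish: int, n_runs: int,
               master_seed: int, tag: Sequence[int],
               snapshot_interval: float = 1.0):
    """Retained-half P/M/D series of n_runs runs at one parameter point."""
    p_all, m_all, d_all = [], [], []
    for r in range(n_runs):
        tr = run_simulation(params, kicks_per_fish,
                            seed=_point_seed(master_seed, *tag, r),
                            snapshot_interval=snapshot_interval)
        df = order_parameters(tr)
        p_all.append(retained_half(df["P"].to_numpy()))
        m_all.append(retained_half(df["M"].to_numpy()))
        d_all.append(retained_half(df["D"].to_numpy()))
    return p_all, m_all, d_all


@dataclass
class PhaseGrid:
    """Run- and time-averaged observables on a (gamma_att, gamma_ali) grid."""

    gamma_att_axis: np.ndarray
    gamma_ali_axis: np.ndarray
    mean_P: np.ndarray       # shape (n_att, n_ali)
    mean_M: np.ndarray
    mean_D: np.ndarray
    phase_labels: np.ndarray  # same shape, dtype str

    def to_dataframe(self):
        """Long-format table: gamma_att, gamma_ali, mean_P, mean_M, mean_D, label."""
        import pandas as pd

        ia, il = np.meshgrid(np.arange(len(self.gamma_att_axis)),
                             np.arange(len(self.gamma_ali_axis)), indexing="ij")
        return pd.DataFrame({
            "gamma_att": self.gamma_att_axis[ia.ravel()],
            "gamma_ali": self.gamma_ali_axis[il.ravel()],
            "mean_P": self.mean_P.ravel(),
            "mean_M": self.mean_M.ravel(),
            "mean_D": self.mean_D.ravel(),
            "label": self.phase_labels.ravel(),
        })


def sweep_phase_diagram(gamma_att_values, gamma_ali_values,
                        base_params: ModelParams, kicks_per_fish: int = 2000,
                        n_runs: int = 5, seed: int = 0,
                        snapshot_interval: float = 1.0) -> PhaseGrid:
    """Average P, M, D over runs at every grid pixel and label its phase.

    Per pixel, ``n_runs`` independent runs of ``kicks_per_fish`` kicks each
    are averaged over their retained (second) halves.  Deterministic given
    ``seed``.
    """
    atts = np.asarray(gamma_att_values, dtype=float)
    alis = np.asarray(gamma_ali_values, dtype=float)
    shape = (len(atts), len(alis))
    mean_p = np.zeros(shape)
    mean_m = np.zeros(shape)
    mean_d = np.zeros(shape)
    labels = np.empty(shape, dtype=object)
    for ia, g_att in enumerate(atts):
        for il, g_ali in enumerate(alis):
            params = base_params.replace(gamma_att=float(g_att),
                                         gamma_ali=float(g_ali))
            p_all, m_all, d_all = _run_point(params, kicks_per_fish, n_runs,
                                             seed, (ia, il), snapshot_interval)
            mean_p[ia, il] = np.mean([a.mean() for a in p_all])
            mean_m[ia, il] = np.mean([a.mean() for a in m_all])
            mean_d[ia, il] = np.mean([a.mean() for a in d_all])
            labels[ia, il] = classify_phase(mean_p[ia, il], mean_m[ia, il],
                                            mean_d[ia, il])
    return PhaseGrid(atts, alis, mean_p, mean_m, mean_d,
                     labels.astype(str))


@dataclass
class TransectResult:
    """Pointwise distributions of instantaneous P and M along a transect."""

    points: list                 # (gamma_att, gamma_ali) per transect point
    bin_edges: np.ndarray
    pdf_P: np.ndarray            # (n_points, n_bins), density normalised
    pdf_M: np.ndarray
    mean_P: np.ndarray
    mean_M: np.ndarray
    mean_D: np.ndarray


def transect_pdf(points, base_params: ModelParams, kicks_per_fish: int = 200,
                 n_runs: int = 20, seed: int = 0, bin_width: float = 0.02,
                 pooled: bool = True) -> TransectResult:
    """PDFs of instantaneous P(t), M(t) at each transect point.

    Histograms pool the retained halves of all runs (``pooled=True``,
    default) or average per-run histograms; bins are fixed width on [0, 1]
    and density-normalised.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    nb = len(edges) - 1
    pdf_p = np.zeros((len(points), nb))
    pdf_m = np.zeros((len(points), nb))
    mp = np.zeros(len(points))
    mm = np.zeros(len(points))
    md = np.zeros(len(points))
    for ip, (g_att, g_ali) in enumerate(points):
        params = base_params.replace(gamma_att=float(g_att),
                                     gamma_ali=float(g_ali))
        p_all, m_all, d_all = _run_point(params, kicks_per_fish, n_runs,
                                         seed, (ip,))
        if pooled:
            pooled_p = np.concatenate(p_all)
            pooled_m = np.concatenate(m_all)
            pdf_p[ip], _ = np.histogram(pooled_p, bins=edges, density=True)
            pdf_m[ip], _ = np.histogram(pooled_m, bins=edges, density=True)
        else:
            pdf_p[ip] = np.mean([np.histogram(a, bins=edges, density=True)[0]
                                 for a in p_all], axis=0)
            pdf_m[ip] = np.mean([np.histogram(a, bins=edges, density=True)[0]
                                 for a in m_all], axis=0)
        mp[ip] = np.mean([a.mean() for a in p_all])
        mm[ip] = np.mean([a.mean() for a in m_all])
        md[ip] = np.mean([a.mean() for a in d_all])
    return TransectResult(list(points), edges, pdf_p, pdf_m, mp, mm, md)


@dataclass
class LongRunSummary:
    """Run-averaged long-term statistics from the fragmentation battery."""

    times: np.ndarray
    mean_D_t: np.ndarray
    mean_DG_t: np.ndarray
    mean_NG_t: np.ndarray
    ng_final: np.ndarray        # per run, NG of the final state
    g1_final: np.ndarray        # per run, size of the largest final group
    d_final: np.ndarray         # per run, final dispersion
    ng_final_pdf: np.ndarray    # P(NG = i), index = NG
    g1_final_pdf: np.ndarray    # P(G1 = s), index = s

    @property
    def frac_single_group(self) -> float:
        """Fraction of runs that end as one single group."""
        return float(np.mean(self.ng_final == 1))

    @property
    def mean_g1_final(self) -> float:
        return float(self.g1_final.mean())

    @property
    def mean_d_final(self) -> float:
        return float(self.d_final.mean())


def long_run_battery(params: ModelParams, n_runs: int, kicks_per_fish: int,
                     a: float = 10.0, b: float = 4.0, seed: int = 0,
                     record_every: float = 20.0) -> LongRunSummary:
    """Long-run dispersion and fragmentation from an aligned ellipse start.

    Fish start with a common heading inside an ellipse of half-axes
    ``a, b`` (inter-fish spacing comparable to a schooling group) and the
    state is recorded every ``record_every`` time units (about every 20
    kicks by default).  Each snapshot is partitioned into groups to track
    the number of groups NG, the largest group G1 and the mean
    within-group dispersion DG; time series are averaged over runs and
    final-state distributions collected.
    """
    d_series, dg_series, ng_series = [], [], []
    ng_final = np.zeros(n_runs, dtype=int)
    g1_final = np.zeros(n_runs, dtype=int)
    d_final = np.zeros(n_runs)
    n_t = None
    for r in range(n_runs):
        tr = run_simulation(params, kicks_per_fish,
                            seed=_point_seed(seed, r), init="ellipse",
                            a=a, b=b, snapshot_interval=record_every)
        df = order_parameters(tr)
        ngs = np.zeros(tr.n_snapshots, dtype=int)
        dgs = np.zeros(tr.n_snapshots)
        for i in range(tr.n_snapshots):
            part = group_snapshot(tr.positions[i], params)
            ngs[i] = part.n_groups
            dgs[i] = part.dg_mean
        d_series.append(df["D"].to_numpy())
        dg_series.append(dgs)
        ng_series.append(ngs)
        ng_final[r] = ngs[-1]
        g1_final[r] = group_snapshot(tr.positions[-1], params).largest
        d_final[r] = df["D"].to_numpy()[-1]
        n_t = tr.n_snapshots if n_t is None else min(n_t, tr.n_snapshots)
    times = np.arange(n_t) * record_every
    mean_d = np.mean([s[:n_t] for s in d_series], axis=0)
    mean_dg = np.mean([s[:n_t] for s in dg_series], axis=0)
    mean_ng = np.mean([s[:n_t] for s in ng_series], axis=0)
    ng_pdf = np.bincount(ng_final) / n_runs
    g1_pdf = np.bincount(g1_final, minlength=params.n_fish + 1) / n_runs
    return LongRunSummary(times, mean_d, mean_dg, mean_ng,
                          ng_final, g1_final, d_final, ng_pdf, g1_pdf)


def find_dispersal_boundary(k: int, base_params: ModelParams,
                            gamma_att_values, gamma_ali_values=(0.2, 0.4, 0.6),
                            kicks_per_fish: int = 1000, n_runs: int = 5,
                            seed: int = 0, extend_to: Optional[float] = None,
                            step: float = 0.02) -> tuple[float, dict]:
    """Smallest attraction strength at which any alignment keeps cohesion.

    A scan point is cohesive when its mean final dispersion over ``n_runs``
    runs is at most 200.  If no scanned attraction value is cohesive and
    ``extend_to`` is given, the attraction axis is extended upward in
    ``step`` increments until a cohesive value is found (or the bound is
    reached, returning nan).  Returns the boundary and the per-point mean
    final dispersions.
    """
    params = base_params.replace(k=k)
    grid: dict[tuple[float, float], float] = {}

    def cohesive_at(g_att: float, ia: int) -> bool:
        found = False
        for il, g_ali in enumerate(gamma_ali_values):
            p = params.replace(gamma_att=float(g_att), gamma_ali=float(g_ali))
            finals = []
            for r in range(n_runs):
                tr = run_simulation(p, kicks_per_fish,
                                    seed=_point_seed(seed, k, ia, il, r))
                rel = tr.positions[-1] - tr.positions[-1].mean(axis=0)
                finals.append(float(np.mean(np.sum(rel * rel, axis=1))))
            grid[(round(float(g_att), 6), float(g_ali))] = float(np.mean(finals))
            if np.mean(finals) <= D_COHESION:
                found = True
        return found

    atts = [float(g) for g in gamma_att_values]
    for ia, g_att in enumerate(atts):
        if cohesive_at(g_att, ia):
            return g_att, grid
    if extend_to is not None:
        g_att = atts[-1] + step
        ia = len(atts)
        while g_att <= extend_to + 1e-9:
            if cohesive_at(g_att, ia):
                return round(g_att, 6), grid
            g_att += step
            ia += 1
    return float("nan"), grid
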