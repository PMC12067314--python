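"""Spatial group detection by the chain-of-offspring method.

Fish whose nearest neighbour lies beyond a critical distance of four times
the attraction range form singleton groups.  Other groups grow by a
nearest-neighbour chain: starting from a seed fish, add its nearest
neighbour, then that fish's nearest neighbour, and so on, until the next
nearest neighbour is already in the group; then a new chain is seeded from
the unassigned fish.  Groups whose member-to-member gap is below the
minimum interaction range min(l_att, l_ali) are finally merged, since such
fish still influence each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .params import ModelParams


@dataclass
class GroupPartition:
    """Partition of the school into spatial groups."""

    labels: np.ndarray                 # per-fish group index, 0..n_groups-1
    dg_per_group: Optional[np.ndarray] = None
    dg_mean: Optional[float] = None    # unweighted mean over groups

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_groups)

    @property
    def largest(self) -> int:
        return int(self.sizes.max())

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.labels == g)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber group labels to 0..k-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def build_groups(positions, l_att: float, method: str = "chain") -> GroupPartition:
    """Partition fish into groups with critical distance 4 * l_att.

    ``method="chain"`` follows the nearest-neighbour chain recursion
    literally; ``method="linkage"`` uses single-linkage connected
    components at the same critical distance (the two agree whenever
    clusters are separated by more than the critical distance).  Chains are
    seeded from unassigned fish in ascending id order; nearest-neighbour
    ties go to the lowest id.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if l_att <= 0:
        raise ValueError("l_att must be > 0")
    critical = 4.0 * l_att
    if n == 1:
        return GroupPartition(np.zeros(1, dtype=int))
    dist = squareform(pdist(positions))
    np.fill_diagonal(dist, np.inf)

    if method == "linkage":
        from scipy.sparse.csgraph import connected_components
        from scipy.sparse import csr_matrix

        adj = csr_matrix(dist <= critical)
        _, labels = connected_components(adj, directed=False)
        return GroupPartition(_relabel(labels))
    if method != "chain":
        raise ValueError(f"unknown method {method!r}")

    labels = np.full(n, -1, dtype=int)
    n_groups = 0
    for seed in range(n):
        if labels[seed] >= 0:
            continue
        labels[seed] = n_groups
        current = seed
        while True:
            # nearest neighbour among fish not claimed by *other* groups
            mask = (labels < 0) | (labels == n_groups)
            mask[current] = False
            if not mask.any():
                break
            row = np.where(mask, dist[current], np.inf)
            nn = int(np.argmin(row))
            if labels[nn] == n_groups or row[nn] > critical:
                break
            labels[nn] = n_groups
            current = nn
        n_groups += 1
    return GroupPartition(labels)


def merge_close_groups(partition: GroupPartition, positions,
                       params: ModelParams) -> GroupPartition:
    """Merge groups whose minimum member-to-member distance is below
    min(l_att, l_ali); merging is transitive (iterated to a fixed point)."""
    positions = np.asarray(positions, dtype=float)
    threshold = min(params.l_att, params.l_ali)
    labels = partition.labels.copy()
    k = partition.n_groups
    if k <= 1:
        return GroupPartition(labels)
    # Two groups are merge-linked iff some cross-group fish pair is below
    # threshold, so union-find over below-threshold fish pairs gives the
    # transitive closure directly; merging cannot create new
    # below-threshold pairs (the min-distance between merged sets is the
    # min over the parts), so this single pass is the fixed point.
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dist = squareform(pdist(positions))
    ii, jj = np.nonzero((dist < threshold)
                        & (labels[:, None] != labels[None, :]))
    for i, j in zip(ii, jj):
        if i < j:
            ra, rb = find(labels[i]), find(labels[j])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    merged = np.array([find(g) for g in labels])
    return GroupPartition(_relabel(merged))


def group_stats(partition: GroupPartition, positions) -> tuple[int, np.ndarray, int, float]:
    """(NG, sizes, G1, DG) of a partition; fills the partition's DG fields.

    DG is the within-group dispersion (mean squared distance to the group's
    own barycentre), averaged over groups with equal weight; singleton
    groups contribute 0.
    """
    positions = np.asarray(positions, dtype=float)
    ng = partition.n_groups
    dg = np.zeros(ng)
    for g in range(ng):
        m = partition.members(g)
        if len(m) > 1:
            rel = positions[m] - positions[m].mean(axis=0)
            dg[g] = float(np.mean(np.sum(rel * rel, axis=1)))
    partition.dg_per_group = dg
    partition.dg_mean = float(dg.mean())
    return ng, partition.sizes, partition.largest, partition.dg_mean


def group_snapshot(positions, params: ModelParams,
                   method: str = "chain") -> GroupPartition:
    """Full pipeline: build groups, merge close ones, compute statistics."""
    part = build_groups(positions, params.l_att, method=method)
    part = merge_close_groups(part, positions, params)
    group_stats(part, positions)
    return part
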