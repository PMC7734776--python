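"""Daura (GROMOS) RMSD clustering and composition/convergence diagnostics.

The algorithm repeatedly takes the structure with the most neighbours
within an RMSD cut-off as a cluster centre, removes the cluster, and
iterates until every frame is assigned.  The neighbour count includes the
candidate centre itself; ties are broken by the lowest frame index, and
clusters are numbered by descending size (so "cluster 1" is always the
most populated conformation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Selection, Trajectory
from .superpose import pairwise_rmsd_matrix, superpose_trajectory


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class Cluster:
    center_frame: int
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Clustering:
    clusters: tuple[Cluster, ...]   # sorted by descending size
    cutoff: float                   # nm
    total_frames: int

    def labels(self) -> np.ndarray:
        """Per-frame cluster rank (0 = largest cluster)."""
        lab = np.full(self.total_frames, -1, dtype=int)
        for rank, c in enumerate(self.clusters):
            lab[list(c.members)] = rank
        return lab

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ClusterError("distance matrix must be square")
    n = matrix.shape[0]
    block = 1024   # blocked checks: no full-matrix temporaries at n ~ 10^4
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        if not np.allclose(matrix[i0:i1], matrix[:, i0:i1].T, atol=1e-9):
            raise ClusterError("distance matrix must be symmetric")
        if np.any(matrix[i0:i1] < 0):
            raise ClusterError("distance matrix has negative entries")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ClusterError("distance matrix must have a zero diagonal")
    return matrix


def daura_cluster(matrix: np.ndarray, cutoff: float) -> Clustering:
    """Greedy neighbour clustering of a symmetric RMSD matrix.

    Among the unassigned frames, the one with the most unassigned
    neighbours at distance <= cutoff (counting itself) becomes a centre;
    it and its neighbours form a cluster and are removed; repeat until all
    frames are assigned.
    """
    matrix = _validate_matrix(matrix)
    if cutoff <= 0:
        raise ClusterError("cutoff must be positive")
    n = matrix.shape[0]
    adjacency = matrix <= cutoff
    unassigned = np.ones(n, dtype=bool)
    raw: list[Cluster] = []
    while unassigned.any():
        counts = adjacency[:, unassigned].sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.nonzero(adjacency[center] & unassigned)[0]
        raw.append(Cluster(center_frame=center, members=tuple(int(i) for i in members)))
        unassigned[members] = False
    ordered = sorted(raw, key=lambda c: (-c.size, c.center_frame))
    return Clustering(clusters=tuple(ordered), cutoff=float(cutoff), total_frames=n)


def cluster_composition(clustering: Clustering, labels) -> pd.DataFrame:
    """Per-cluster, per-system occupancy fractions.

    For each cluster and system label the fraction is (members with that
    label) / (total frames of that system), so statements like "82.5% of
    the apo structures fall in cluster 2" are directly reproducible.  Rows
    are cluster ranks (0-based, size-ordered), columns system labels; each
    column sums to 1.
    """
    labels = list(labels)
    if len(labels) != clustering.total_frames:
        raise ClusterError(
            f"{len(labels)} labels for {clustering.total_frames} frames"
        )
    labels_arr = np.asarray(labels)
    systems = sorted(set(labels))
    totals = {s: int(np.sum(labels_arr == s)) for s in systems}
    data = np.zeros((clustering.n_clusters, len(systems)))
    for rank, c in enumerate(clustering.clusters):
        member_labels = labels_arr[list(c.members)]
        for j, s in enumerate(systems):
            data[rank, j] = np.sum(member_labels == s) / totals[s]
    return pd.DataFrame(data, columns=systems,
                        index=pd.RangeIndex(clustering.n_clusters, name="cluster"))


def cutoff_sweep(matrix: np.ndarray, cutoffs) -> list[tuple[float, int]]:
    """Cluster count at each cut-off (diagnostic for cut-off choice)."""
    if any(c <= 0 for c in cutoffs):
        raise ClusterError("cutoffs must be positive")
    return [(float(c), daura_cluster(matrix, c).n_clusters) for c in cutoffs]


def incremental_cluster_count(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Selection,
    cutoff: float,
    window: float,
    pairwise_fit: bool = False,
) -> list[tuple[float, int]]:
    """Cluster counts on growing trajectory prefixes (convergence check).

    The trajectory is cut at multiples of ``window`` (ps); for each prefix
    the RMSD matrix is recomputed and clustered.  A levelling-off of the
    count indicates the ensemble has stopped discovering new
    conformations.  The count is not guaranteed monotone and is reported
    as observed.  By default frames are fitted once to the first frame
    (``pairwise_fit=True`` switches to per-pair fitting).
    """
    times = traj.times()
    duration = times[-1] - times[0]
    if window <= 0 or duration / window < 2:
        raise ClusterError("window must cut the trajectory into >= 2 prefixes")
    edges = np.arange(times[0] + window, times[0] + duration + window / 2, window)
    out: list[tuple[float, int]] = []
    fitted = superpose_trajectory(traj, traj.frames[0], fit_sel)
    for edge in edges:
        n_pref = int(np.sum(times <= edge + 1e-9))
        if n_pref < 2:
            continue
        prefix = Trajectory(traj.topology, traj.frames[:n_pref])
        if pairwise_fit:
            mat = pairwise_rmsd_matrix(prefix, fit_sel, measure_sel)
        else:
            pre = Trajectory(fitted.topology, fitted.frames[:n_pref])
            mat = pairwise_rmsd_matrix(pre, None, measure_sel)
        out.append((float(edge - times[0]), daura_cluster(mat, cutoff).n_clusters))
    return out
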