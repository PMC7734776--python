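"""Non-metric multidimensional scaling of cluster-centre distances.

A random 2D configuration is iteratively rearranged so that the rank order
of its inter-point distances matches the rank order of the input RMSD
dissimilarities.  Disparities come from monotone (isotonic) regression of
the configuration distances on the dissimilarity ranks (Kruskal's primary
approach to ties: tied dissimilarities may keep distinct disparities);
the configuration update is the Guttman transform.  Badness of fit is
Kruskal's stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

and iteration stops once the stress improvement falls below a tolerance.
An update that would increase stress is rejected and terminates the run,
so the reported stress sequence is non-increasing by construction.
Several random restarts are made and the lowest-stress embedding kept;
everything is reproducible from the seed.  The final configuration is
rescaled so embedded distances are least-squares matched to the input
dissimilarities, which makes distance thresholds on the embedding
interpretable in the input units (nm for RMSD input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

import pandas as pd

from .cluster import Clustering


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class Embedding:
    points: np.ndarray        # (n, dim)
    stress: float             # Kruskal stress-1
    seed: int
    iterations: int
    stress_history: tuple[float, ...] = ()


@dataclass(frozen=True)
class MetaClustering:
    assignment: tuple[int, ...]      # per-embedded-cluster meta-cluster id
    linkage_threshold: float

    @property
    def n_metaclusters(self) -> int:
        return len(set(self.assignment))


def _stress_and_disparities(d: np.ndarray, order: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 of distances d given the dissimilarity rank order.

    The disparities are renormalized to the same total square sum as the
    distances, which pins the configuration scale across Guttman updates
    (otherwise the free overall scale lets the normalized stress drift
    upward even as the raw stress decreases).
    """
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    denom = np.sum(d ** 2)
    if denom == 0:
        return np.inf, dhat
    ssq = np.sum(dhat ** 2)
    if ssq > 0:
        dhat = dhat * np.sqrt(denom / ssq)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom)), dhat


def _classical_init(delta: np.ndarray, dim: int) -> np.ndarray:
    """Classical-scaling (PCoA) configuration used to anchor restart 0."""
    d2 = delta ** 2
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dim]
    return vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))


def _single_run(
    delta: np.ndarray, dim: int, x0: np.ndarray,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, float, int, list[float]]:
    n = delta.shape[0]
    dvec = squareform(delta, checks=False)
    # primary tie approach: within a tie block, order by nothing in
    # particular (stable index order) — tied delta may take distinct dhat
    order = np.argsort(dvec, kind="stable")
    x = x0
    d = pdist(x)
    stress, dhat = _stress_and_disparities(d, order)
    history = [stress]
    iters = 0
    for iters in range(1, max_iter + 1):
        # Guttman transform with current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        b = -squareform(ratio, checks=False)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = (b @ x) / n
        d_new = pdist(x_new)
        stress_new, dhat_new = _stress_and_disparities(d_new, order)
        if stress_new > stress:          # monotone safeguard: never report an increase
            break
        improved = stress - stress_new
        x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
        history.append(stress)
        if improved < tol:
            break
    return x, stress, iters, history


def nonmetric_mds(
    distances: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 4,
) -> Embedding:
    """Embed a symmetric dissimilarity matrix by non-metric MDS."""
    delta = np.asarray(distances, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise OrdinationError("distance matrix must be square")
    if not np.allclose(delta, delta.T, atol=1e-9):
        raise OrdinationError("distance matrix must be symmetric")
    n = delta.shape[0]
    if n < 3:
        raise OrdinationError("need at least 3 points to embed")
    if np.all(delta == 0):
        raise OrdinationError("all dissimilarities are zero")

    # Restart 0 starts from the classical-scaling solution: with small
    # centre sets and heavily tied dissimilarities, purely random starts
    # admit degenerate rank-preserving distortions; anchoring one restart
    # at the metric geometry keeps near-embeddable inputs undistorted.
    # Further restarts are random from the seed and win only on a strict
    # stress improvement beyond tol.
    dvec = squareform(delta, checks=False)
    best = None
    for r in range(n_restarts):
        if r == 0:
            x0 = _classical_init(delta, dim)
        else:
            rng = np.random.default_rng([seed, r])
            x0 = rng.normal(scale=np.mean(dvec), size=(n, dim))
        x, stress, iters, history = _single_run(delta, dim, x0, max_iter, tol)
        if best is None or stress < best[1] - tol:
            best = (x, stress, iters, history)
    x, stress, iters, history = best

    # least-squares scale match of embedded distances to the input
    # dissimilarities (stress-1 is scale invariant, so this is free)
    d = pdist(x)
    dvec = squareform(delta, checks=False)
    scale = float(np.dot(dvec, d) / np.dot(d, d))
    x = (x - x.mean(axis=0)) * scale
    return Embedding(points=x, stress=stress, seed=seed, iterations=iters,
                     stress_history=tuple(history))


def group_metaclusters(embedding: Embedding, linkage_threshold: float) -> MetaClustering:
    """Single-linkage connected components of the embedded points.

    Replaces the by-eye circling of nearby cluster centres with a
    deterministic rule: two centres belong to the same meta-cluster when a
    chain of centres at pairwise embedded distance <= threshold connects
    them.  Meta-cluster ids are numbered by each component's lowest point
    index.
    """
    if linkage_threshold <= 0:
        raise OrdinationError("linkage threshold must be positive")
    pts = embedding.points
    d = squareform(pdist(pts))
    adj = csr_matrix(d <= linkage_threshold)
    _, raw = connected_components(adj, directed=False)
    # relabel deterministically by first occurrence
    remap: dict[int, int] = {}
    out = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    return MetaClustering(assignment=tuple(out), linkage_threshold=float(linkage_threshold))


def metacluster_occupancy(
    meta: MetaClustering,
    clustering: Clustering,
    labels,
    embedded_clusters: list[int] | None = None,
) -> pd.DataFrame:
    """Per-system fraction of time spent in each meta-cluster.

    ``embedded_clusters`` lists the cluster ranks that were embedded
    (default: the first len(meta.assignment) size-ordered clusters).
    Frames in clusters beyond the embedded set are reported in an explicit
    "unassigned" column, so per-system fractions sum to 1 including it.
    """
    labels = np.asarray(list(labels))
    if len(labels) != clustering.total_frames:
        raise OrdinationError("label count does not match clustering")
    if embedded_clusters is None:
        embedded_clusters = list(range(len(meta.assignment)))
    if len(embedded_clusters) != len(meta.assignment):
        raise OrdinationError(
            f"meta-clustering covers {len(meta.assignment)} clusters but "
            f"{len(embedded_clusters)} were embedded"
        )
    if max(embedded_clusters, default=-1) >= clustering.n_clusters:
        raise OrdinationError("embedded cluster rank out of range")

    frame_cluster = clustering.labels()
    cluster_to_meta = {c: m for c, m in zip(embedded_clusters, meta.assignment)}
    meta_ids = sorted(set(meta.assignment))
    systems = sorted(set(labels.tolist()))
    cols = [f"meta_{m}" for m in meta_ids] + ["unassigned"]
    table = pd.DataFrame(0.0, index=pd.Index(systems, name="system"), columns=cols)
    for s in systems:
        mask = labels == s
        total = int(mask.sum())
        ranks = frame_cluster[mask]
        for m in meta_ids:
            in_meta = np.isin(ranks, [c for c, mm in cluster_to_meta.items() if mm == m])
            table.loc[s, f"meta_{m}"] = in_meta.sum() / total
        assigned = np.isin(ranks, embedded_clusters)
        table.loc[s, "unassigned"] = (~assigned).sum() / total
    return table
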