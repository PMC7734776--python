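"""Least-squares rigid-body superposition and RMSF/RMSD descriptors.

All fits are unweighted (the descriptors are defined on plain coordinates
and the fit groups are typically C-alpha only).  The superposition is the
Kabsch algorithm: SVD of the cross-covariance with the determinant-sign
correction, so only proper rotations are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Selection, Trajectory


class FitError(ValueError):
    """Raised for degenerate superposition inputs."""


@dataclass(frozen=True)
class FitResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # nm
    fit_rmsd: float           # nm, over the fit selection

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


def _check_fit_coords(p: np.ndarray) -> None:
    if p.shape[0] < 3:
        raise FitError("need at least 3 atoms in the fit selection")
    centered = p - p.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise FitError("fit selection is collinear or degenerate")


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R p + t - q||^2 (unweighted)."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    return rot, trans


def kabsch_fit(mobile: Frame, reference: Frame, fit_sel: Selection) -> FitResult:
    """Optimal rigid superposition of the mobile frame onto the reference.

    Returns the proper rotation and translation minimizing the sum of
    squared deviations over ``fit_sel``, together with the residual RMSD.
    """
    idx = fit_sel.as_array()
    p = mobile.coordinates[idx]
    q = reference.coordinates[idx]
    _check_fit_coords(p)
    _check_fit_coords(q)
    rot, trans = _kabsch(p, q)
    fitted = p @ rot.T + trans
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return FitResult(rotation=rot, translation=trans, fit_rmsd=fit_rmsd)


def rmsd(
    frame: Frame,
    reference: Frame,
    fit_sel: Selection,
    measure_sel: Selection,
) -> float:
    """RMSD over ``measure_sel`` after a least-squares fit over ``fit_sel``.

    sqrt( (1/N) sum_i ||x_i - x_i(ref)||^2 ) with N = |measure_sel|,
    evaluated after the frame has been rigidly fitted onto the reference
    over the (possibly different) fit selection — e.g. loop atoms measured
    after fitting the flanking C-alpha backbone.
    """
    fit = kabsch_fit(frame, reference, fit_sel)
    idx = measure_sel.as_array()
    moved = fit.apply(frame.coordinates[idx])
    diff = moved - reference.coordinates[idx]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def superpose_trajectory(
    traj: Trajectory, reference: Frame, fit_sel: Selection
) -> Trajectory:
    """Fit every frame to the reference over ``fit_sel`` (new trajectory)."""
    frames = []
    for f in traj.frames:
        fit = kabsch_fit(f, reference, fit_sel)
        frames.append(
            Frame(fit.apply(f.coordinates), time=f.time, system_label=f.system_label)
        )
    return Trajectory(traj.topology, frames)


def rmsf(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Selection,
    fit_reference: Frame | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-averaged position.

    Each frame is first fitted to ``fit_reference`` (default: the first
    frame) over ``fit_sel``; for each atom in ``measure_sel`` the result is
    sqrt( (1/T) sum_t ||x(t) - xbar||^2 ) with xbar the mean fitted
    position of that atom.  A mean structure may be passed as the fit
    reference instead of the first frame.
    """
    if traj.n_frames < 2:
        raise FitError("RMSF needs at least 2 frames")
    if fit_reference is None:
        fit_reference = traj.frames[0]
    fitted = superpose_trajectory(traj, fit_reference, fit_sel)
    idx = measure_sel.as_array()
    coords = fitted.coordinate_array()[:, idx, :]   # (T, N, 3)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def average_frame(traj: Trajectory, fit_sel: Selection) -> Frame:
    """Mean structure after fitting every frame to the first frame."""
    fitted = superpose_trajectory(traj, traj.frames[0], fit_sel)
    return Frame(fitted.coordinate_array().mean(axis=0))


def _batched_kabsch_rmsd(
    coords: np.ndarray,
    ref_index: int,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray,
) -> np.ndarray:
    """RMSD of every frame to frame ``ref_index`` with per-pair fitting."""
    p = coords[:, fit_idx, :]
    q = coords[ref_index, fit_idx, :]
    pc = p.mean(axis=1, keepdims=True)
    qc = q.mean(axis=0)
    h = np.einsum("fni,nj->fij", p - pc, q - qc)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", vt.transpose(0, 2, 1),
                                  u.transpose(0, 2, 1)))
    corr = np.repeat(np.eye(3)[None], coords.shape[0], axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", vt.transpose(0, 2, 1), corr,
                    u.transpose(0, 2, 1))
    trans = qc - np.einsum("fij,fj->fi", rot, pc[:, 0, :])
    m = coords[:, measure_idx, :]
    moved = np.einsum("fij,fnj->fni", rot, m) + trans[:, None, :]
    diff = moved - coords[ref_index, measure_idx, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


def pairwise_rmsd_matrix(
    traj: Trajectory,
    fit_sel: Selection | None,
    measure_sel: Selection,
) -> np.ndarray:
    """All-against-all RMSD matrix over ``measure_sel`` (nm).

    With ``fit_sel`` given, every pair (i, j) is superposed independently
    over the fit selection before measuring (M[i, j] = rmsd(frame_j,
    frame_i)); the result is symmetrized and has a zero diagonal.  With
    ``fit_sel=None`` frames are compared as-is (use
    :func:`superpose_trajectory` first to reproduce the fit-once-to-first-
    frame protocol, which is much faster for large ensembles and identical
    when the fit group is rigid).
    """
    if traj.n_frames < 2:
        raise FitError("need at least 2 frames")
    coords = traj.coordinate_array()
    m_idx = measure_sel.as_array()
    n = coords.shape[0]
    if fit_sel is None:
        # Gram-matrix route, in place: a single n x n buffer so 10^4-frame
        # ensembles stay well under a couple of GB
        flat = np.ascontiguousarray(coords[:, m_idx, :].reshape(n, -1))
        sq = np.einsum("ij,ij->i", flat, flat)
        mat = flat @ flat.T
        mat *= -2.0
        mat += sq[:, None]
        mat += sq[None, :]
        mat /= len(m_idx)
        np.maximum(mat, 0.0, out=mat)
        np.sqrt(mat, out=mat)
    else:
        f_idx = fit_sel.as_array()
        _check_fit_coords(coords[0, f_idx, :])
        mat = np.empty((n, n), dtype=float)
        for i in range(n):
            mat[i] = _batched_kabsch_rmsd(coords, i, f_idx, m_idx)
    # blocked in-place symmetrization (avoids a full n x n temporary)
    block = 1024
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        mat[i0:i1] = 0.5 * (mat[i0:i1] + mat[:, i0:i1].T)
        mat[:, i0:i1] = mat[i0:i1].T
    np.fill_diagonal(mat, 0.0)
    return mat
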