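"""Geometric hydrogen-bond detection and short-range non-bonded energies.

Hydrogen bonds use the donor-acceptor distance plus an angular criterion.
The default angle convention is acceptor-donor-hydrogen: the hydrogen may
deviate at most ``angle_cutoff`` degrees from the donor->acceptor axis,
measured at the donor (a 30 degree cone).  The alternative convention
``"DHA"`` instead requires the donor-hydrogen-acceptor angle, measured at
the hydrogen, to be >= 180 - angle_cutoff (i.e. near-linear).

Energies are plain truncated pair sums between two disjoint groups:

    E_Coul = sum f q_i q_j / r_ij          f = 138.935458 kJ mol^-1 nm e^-2
    E_LJ   = sum C12_ij / r_ij^12 - C6_ij / r_ij^6

with geometric-mean combination of the per-atom C6/C12 parameters and a
real-space cut-off (default 1.4 nm).  No switching function and no
long-range correction: only the short-range terms are accounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Frame, Selection, Topology, Trajectory

COULOMB_CONSTANT = 138.935458  # kJ mol^-1 nm e^-2


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float   # donor-acceptor, nm
    angle: float      # degrees, in the chosen convention


@dataclass(frozen=True)
class EnergyPair:
    e_coulomb: float
    e_lj: float

    @property
    def e_total(self) -> float:
        return self.e_coulomb + self.e_lj


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hbonds(
    frame: Frame,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
    dist_cutoff: float = 0.35,
    angle_cutoff: float = 30.0,
    angle_convention: str = "ADH",
) -> list[HBond]:
    """All hydrogen bonds between two groups in one frame.

    Donor (with its bonded hydrogen) in one group, acceptor in the other,
    in both directions; exhaustive over candidate triples.  Criteria:
    donor-acceptor distance <= ``dist_cutoff`` and the angular test of the
    chosen convention (see module docstring).
    """
    if angle_convention not in ("ADH", "DHA"):
        raise InteractionError(f"unknown angle convention {angle_convention!r}")
    coords = frame.coordinates
    set_a = set(group_a.indices)
    set_b = set(group_b.indices)
    roles = [a.hbond_role for a in topology.atoms]
    dh_pairs = topology.donor_hydrogen_pairs()

    out: list[HBond] = []
    for donors_in, acceptors_in in ((set_a, set_b), (set_b, set_a)):
        acceptors = [i for i in sorted(acceptors_in) if roles[i] == "acceptor"]
        for d, h in dh_pairs:
            if d not in donors_in or roles[d] != "donor":
                continue
            for acc in acceptors:
                if acc == d:
                    continue
                r_da = float(np.linalg.norm(coords[acc] - coords[d]))
                if r_da > dist_cutoff:
                    continue
                if angle_convention == "ADH":
                    ang = _angle_deg(coords[h] - coords[d], coords[acc] - coords[d])
                    ok = ang <= angle_cutoff
                else:
                    ang = _angle_deg(coords[d] - coords[h], coords[acc] - coords[h])
                    ok = ang >= 180.0 - angle_cutoff
                if ok:
                    out.append(HBond(d, h, acc, distance=r_da, angle=ang))
    out.sort(key=lambda b: (b.donor_index, b.hydrogen_index, b.acceptor_index))
    return out


def hbond_count_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    dist_cutoff: float = 0.35,
    angle_cutoff: float = 30.0,
    angle_convention: str = "ADH",
) -> np.ndarray:
    """Number of inter-group hydrogen bonds in every frame."""
    return np.array([
        len(find_hbonds(f, traj.topology, group_a, group_b,
                        dist_cutoff, angle_cutoff, angle_convention))
        for f in traj.frames
    ], dtype=int)


def hbond_histogram(series) -> dict[int, int]:
    """Frequency of each hydrogen-bond count; frequencies sum to the frame count."""
    series = np.asarray(series, dtype=int)
    if series.size == 0:
        raise InteractionError("empty hydrogen-bond series")
    values, counts = np.unique(series, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def pairwise_nonbonded_energy(
    frame: Frame,
    topology: Topology,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 1.4,
) -> EnergyPair:
    """Truncated Coulomb + Lennard-Jones energy between two disjoint groups."""
    ia = group_a.as_array()
    ib = group_b.as_array()
    if np.intersect1d(ia, ib).size:
        raise InteractionError("interaction groups must be disjoint")
    ra = frame.coordinates[ia]
    rb = frame.coordinates[ib]
    r = cdist(ra, rb)
    mask = r <= cutoff
    if np.any(mask & (r == 0.0)):
        raise InteractionError("zero inter-atomic distance (singular pair)")
    if not mask.any():
        return EnergyPair(0.0, 0.0)
    rm = r[mask]
    qq = np.outer(topology.charges[ia], topology.charges[ib])[mask]
    c6 = np.sqrt(np.outer(topology.lj_c6[ia], topology.lj_c6[ib]))[mask]
    c12 = np.sqrt(np.outer(topology.lj_c12[ia], topology.lj_c12[ib]))[mask]
    e_coul = COULOMB_CONSTANT * np.sum(qq / rm)
    e_lj = np.sum(c12 / rm ** 12 - c6 / rm ** 6)
    return EnergyPair(float(e_coul), float(e_lj))


def energy_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 1.4,
) -> pd.DataFrame:
    """Per-frame short-range energies as a table (frame, e_coul, e_lj, e_total)."""
    rows = []
    for i, f in enumerate(traj.frames):
        e = pairwise_nonbonded_energy(f, traj.topology, group_a, group_b, cutoff)
        rows.append((i, f.time, e.e_coulomb, e.e_lj, e.e_total))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "e_coul", "e_lj", "e_total"])


def energy_histogram(series, bin_width: float) -> dict[float, int]:
    """Histogram of per-frame energies in half-open bins [k*w, (k+1)*w).

    A value exactly on a bin edge belongs to the higher bin.  Keys are the
    left bin edges (kJ/mol); counts sum to the frame count.
    """
    if bin_width <= 0:
        raise InteractionError("bin width must be positive")
    series = np.asarray(series, dtype=float)
    ks = np.floor(series / bin_width).astype(int)
    values, counts = np.unique(ks, return_counts=True)
    return {float(k * bin_width): int(c) for k, c in zip(values, counts)}
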