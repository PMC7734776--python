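"""Synthetic multi-conformation loop trajectories and interaction fixtures.

The generator emulates the statistical structure of a receptor loop that
switches among K planted conformations while the flanking scaffold stays
rigid up to small Gaussian noise: a beta-hairpin-like loop of eight
residues bridging two six-residue flanking strands.  Loop conformations
are generated by rotating the loop arc about the axis through its two
anchor points (a one-parameter pseudo-dihedral deformation), which gives
direct control over inter-state RMSD.  Frames carry a system label so
cross-system cluster composition is computable, and true state labels are
returned for recovery scoring.

None of this is physically realistic dynamics — no force field, no
solvent, no correlated motions beyond optional Markov switching — it is
the minimal geometry needed to exercise superposition, clustering,
ordination and the interaction kernels end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Atom, BondTable, Frame, Selection, Topology, Trajectory

# residue layout: strand A = residues 1..6, loop = 7..14, strand B = 15..20
N_FLANK = 6
N_LOOP = 8
STRAND_SPACING = 0.38   # nm, consecutive C-alpha distance in a strand
DEFAULT_RADIUS = 0.7    # nm, loop arc radius

# rigid intra-residue offsets (nm) relative to the C-alpha trace point
_OFFSET_N = np.array([-0.10, 0.04, 0.0])
_OFFSET_O = np.array([0.10, -0.04, 0.0])
_OFFSET_HN = np.array([-0.10, 0.14, 0.0])   # H sits 0.10 nm "above" N


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class LoopSystem:
    """Topology plus planted state templates for one synthetic receptor."""

    topology: Topology
    loop_sel: Selection          # all loop atoms (the measured group)
    scaffold_sel: Selection      # all flanking-strand atoms
    flanking_ca_sel: Selection   # flanking C-alpha only (the fit group)
    state_templates: np.ndarray  # (K, n_loop_atoms, 3) nm
    scaffold_template: np.ndarray  # (n_scaffold_atoms, 3) nm


def _loop_trace(radius: float, angle_deg: float) -> np.ndarray:
    """C-alpha trace of the loop arc, rotated about the anchor axis (x)."""
    theta = np.pi * (1.0 - (np.arange(N_LOOP) + 1.0) / (N_LOOP + 1.0))
    center_x = radius
    base = np.stack([
        center_x + radius * np.cos(theta),
        radius * np.sin(theta),
        np.zeros(N_LOOP),
    ], axis=1)
    phi = np.radians(angle_deg)
    rot = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(phi), -np.sin(phi)],
        [0.0, np.sin(phi), np.cos(phi)],
    ])
    return base @ rot.T


def _strand_traces(radius: float) -> tuple[np.ndarray, np.ndarray]:
    ys = -STRAND_SPACING * np.arange(N_FLANK, 0, -1)
    a = np.stack([np.zeros(N_FLANK), ys, np.zeros(N_FLANK)], axis=1)
    b = np.stack([np.full(N_FLANK, 2 * radius), ys[::-1], np.zeros(N_FLANK)], axis=1)
    return a, b


def make_loop_system(
    state_angles_deg,
    radius: float = DEFAULT_RADIUS,
) -> LoopSystem:
    """Build the hairpin topology and one loop template per planted state.

    ``state_angles_deg`` are the arc rotation angles about the anchor axis;
    their pairwise differences set the inter-state loop RMSD (roughly
    ``2 * 0.71 * radius * sin(dphi/2)`` over the C-alpha trace).
    """
    strand_a, strand_b = _strand_traces(radius)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    loop_idx: list[int] = []
    scaffold_idx: list[int] = []
    flank_ca_idx: list[int] = []
    scaffold_coords: list[np.ndarray] = []
    loop_local: list[np.ndarray] = []   # per-atom offset + trace slot
    loop_slots: list[int] = []          # which trace point each loop atom follows

    def add_atom(name, resnum, role, charge, c6, c12, coord, is_loop, slot=None):
        i = len(atoms)
        atoms.append(Atom(
            index=i, name=name, element=name[0], residue_number=resnum,
            residue_name="GLY", chain_id="A", charge=charge,
            lj_c6=c6, lj_c12=c12, hbond_role=role,
        ))
        if is_loop:
            loop_idx.append(i)
            loop_slots.append(slot)
            loop_local.append(coord)
        else:
            scaffold_idx.append(i)
            scaffold_coords.append(coord)
        return i

    def add_residue(resnum, trace, is_loop, slot=None):
        n_role = "donor" if is_loop else "none"
        i_n = add_atom("N", resnum, n_role, -0.30, 2.4e-3, 2.0e-6,
                       _OFFSET_N if is_loop else trace + _OFFSET_N, is_loop, slot)
        i_ca = add_atom("CA", resnum, "none", 0.30, 6.0e-3, 1.0e-5,
                        np.zeros(3) if is_loop else trace, is_loop, slot)
        if not is_loop:
            flank_ca_idx.append(i_ca)
        add_atom("O", resnum, "acceptor", -0.40, 2.3e-3, 1.0e-6,
                 _OFFSET_O if is_loop else trace + _OFFSET_O, is_loop, slot)
        if is_loop:
            i_h = add_atom("HN", resnum, "hydrogen", 0.40, 0.0, 0.0,
                           _OFFSET_HN, True, slot)
            bonds.append((i_n, i_h))

    for r in range(N_FLANK):
        add_residue(r + 1, strand_a[r], is_loop=False)
    for r in range(N_LOOP):
        add_residue(N_FLANK + 1 + r, None, is_loop=True, slot=r)
    for r in range(N_FLANK):
        add_residue(N_FLANK + N_LOOP + 1 + r, strand_b[r], is_loop=False)

    topology = Topology(atoms, BondTable(tuple(bonds)))
    templates = []
    for ang in state_angles_deg:
        trace = _loop_trace(radius, ang)
        templates.append(np.array([trace[s] + off
                                   for s, off in zip(loop_slots, loop_local)]))
    return LoopSystem(
        topology=topology,
        loop_sel=Selection(tuple(loop_idx), name="loop"),
        scaffold_sel=Selection(tuple(scaffold_idx), name="scaffold"),
        flanking_ca_sel=Selection(tuple(flank_ca_idx), name="flanking-CA"),
        state_templates=np.array(templates),
        scaffold_template=np.array(scaffold_coords),
    )


@dataclass
class StatePlan:
    """Everything needed to generate one system's labelled ensemble."""

    system: LoopSystem
    occupancies: tuple[float, ...]        # stationary state probabilities
    n_frames: int
    seed: int
    system_label: str = ""
    switching: str | np.ndarray = "independent"  # or a KxK Markov matrix
    noise_sigma: float = 0.02             # nm per coordinate, loop atoms
    scaffold_sigma: float = 0.005         # nm per coordinate, scaffold atoms
    rigid_motion: bool = False            # small global rigid motion per frame
    rigid_motion_angle_deg: float = 3.0
    rigid_motion_translation: float = 0.05
    time_step_ps: float = 10.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        k = self.system.state_templates.shape[0]
        if occ.shape != (k,):
            raise SyntheticError(
                f"{len(occ)} occupancies for {k} state templates"
            )
        if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-12:
            raise SyntheticError("occupancies must be >= 0 and sum to 1")
        if isinstance(self.switching, np.ndarray):
            t = self.switching
            if t.shape != (k, k) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
                raise SyntheticError("Markov matrix rows must be probabilities summing to 1")
        elif self.switching != "independent":
            raise SyntheticError("switching must be 'independent' or a Markov matrix")
        if self.n_frames < 1:
            raise SyntheticError("n_frames must be >= 1")


def _template_separations(templates: np.ndarray, active: np.ndarray) -> float:
    n_atoms = templates.shape[1]
    best = np.inf
    act = np.nonzero(active)[0]
    for i in range(len(act)):
        for j in range(i + 1, len(act)):
            d = templates[act[i]] - templates[act[j]]
            best = min(best, float(np.sqrt(np.sum(d ** 2) / n_atoms)))
    return best


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def generate_loop_ensemble(plan: StatePlan) -> tuple[Trajectory, np.ndarray]:
    """Generate a labelled trajectory with the planted state structure.

    Per frame a state is drawn (independently or by the Markov chain
    started from its stationary occupancies); loop atoms take that state's
    template plus isotropic Gaussian noise, scaffold atoms the scaffold
    template plus smaller noise, and optionally the whole frame undergoes
    a small random rigid motion (exercising the fitting stage).  Returns
    the trajectory and the true per-frame state labels.
    """
    sys_ = plan.system
    occ = np.asarray(plan.occupancies, dtype=float)
    # independent streams so toggling rigid motion leaves noise draws intact
    rng = np.random.default_rng([plan.seed, 0])
    rng_noise = np.random.default_rng([plan.seed, 1])
    rng_motion = np.random.default_rng([plan.seed, 2])
    sep = _template_separations(sys_.state_templates, occ > 0)
    if sep <= 4 * plan.noise_sigma:
        warnings.warn(
            f"planted templates separated by only {sep:.3f} nm RMSD "
            f"(< 4 x noise sigma = {4 * plan.noise_sigma:.3f} nm); "
            "states may not be recoverable", stacklevel=2,
        )

    k = len(occ)
    if isinstance(plan.switching, np.ndarray):
        states = np.empty(plan.n_frames, dtype=int)
        states[0] = rng.choice(k, p=occ)
        for t in range(1, plan.n_frames):
            states[t] = rng.choice(k, p=plan.switching[states[t - 1]])
    else:
        states = rng.choice(k, size=plan.n_frames, p=occ)

    n_atoms = sys_.topology.n_atoms
    loop_idx = sys_.loop_sel.as_array()
    scaf_idx = sys_.scaffold_sel.as_array()
    frames: list[Frame] = []
    for t in range(plan.n_frames):
        coords = np.zeros((n_atoms, 3))
        coords[scaf_idx] = sys_.scaffold_template
        if plan.scaffold_sigma > 0:
            coords[scaf_idx] += rng_noise.normal(scale=plan.scaffold_sigma,
                                                 size=(len(scaf_idx), 3))
        coords[loop_idx] = sys_.state_templates[states[t]]
        if plan.noise_sigma > 0:
            coords[loop_idx] += rng_noise.normal(scale=plan.noise_sigma,
                                                 size=(len(loop_idx), 3))
        if plan.rigid_motion:
            rot = _random_rotation(rng_motion, plan.rigid_motion_angle_deg)
            trans = rng_motion.uniform(-plan.rigid_motion_translation,
                                       plan.rigid_motion_translation, size=3)
            coords = coords @ rot.T + trans
        frames.append(Frame(coords, time=t * plan.time_step_ps,
                            system_label=plan.system_label))
    return Trajectory(sys_.topology, frames), states


# ---------------------------------------------------------------------------
# bundled multi-system study plan
# ---------------------------------------------------------------------------

# Six planted loop conformations in three well-separated groups of two
# ("meta-states" I, II, III); the three systems draw from them with
# occupancies patterned on an apo receptor (80% in II, 20% in I), a
# ligand that induces a unique conformation (70% I, 30% III) and a
# ligand that locks the shared conformation (100% I).
META_STATE_ANGLES = (-15.0, 15.0, 105.0, 135.0, 225.0, 255.0)
META_OF_STATE = (0, 0, 1, 1, 2, 2)   # meta-state I, II, III as 0, 1, 2
DEFAULT_SYSTEM_OCCUPANCIES = {
    "apo":  (0.10, 0.10, 0.70, 0.10, 0.00, 0.00),   # I 20% / II 80%
    "ligA": (0.45, 0.25, 0.00, 0.00, 0.25, 0.05),   # I 70% / III 30%
    "ligB": (0.85, 0.15, 0.00, 0.00, 0.00, 0.00),   # I 100%
}


def default_study_plans(
    n_frames: int,
    seed: int,
    rigid_motion: bool = True,
    noise_sigma: float = 0.02,
) -> tuple[LoopSystem, list[StatePlan]]:
    """The bundled three-system plan (apo / ligand A / ligand B)."""
    system = make_loop_system(META_STATE_ANGLES)
    plans = []
    for i, (label, occ) in enumerate(sorted(DEFAULT_SYSTEM_OCCUPANCIES.items())):
        plans.append(StatePlan(
            system=system, occupancies=occ, n_frames=n_frames,
            seed=seed + 7919 * (i + 1), system_label=label,
            noise_sigma=noise_sigma, rigid_motion=rigid_motion,
        ))
    return system, plans


# ---------------------------------------------------------------------------
# interaction fixtures
# ---------------------------------------------------------------------------

def generate_hbond_fixture(
    schedule,
    on_distance: float = 0.29,
    on_angle_deg: float = 5.0,
    off_distance: float = 0.45,
) -> tuple[Trajectory, Selection, Selection]:
    """Donor/hydrogen vs acceptor pair with a planted on/off bond schedule.

    On-frames place the acceptor at ``on_distance`` from the donor with an
    acceptor-donor-hydrogen angle of ``on_angle_deg``; off-frames move it
    to ``off_distance`` (violating the distance criterion).  The detector
    output must equal the schedule exactly.
    """
    atoms = [
        Atom(0, "N", "N", 1, "GLY", "A", charge=-0.3, hbond_role="donor"),
        Atom(1, "HN", "H", 1, "GLY", "A", charge=0.3, hbond_role="hydrogen"),
        Atom(2, "O", "O", 2, "GLY", "A", charge=-0.4, hbond_role="acceptor"),
    ]
    top = Topology(atoms, BondTable(((0, 1),)))
    ang = np.radians(on_angle_deg)
    frames = []
    for t, on in enumerate(schedule):
        d = on_distance if on else off_distance
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.10, 0.0, 0.0],                       # H along +x from donor
            [d * np.cos(ang), d * np.sin(ang), 0.0],  # acceptor off-axis by ang
        ])
        frames.append(Frame(coords, time=t * 10.0))
    return Trajectory(top, frames), Selection((0, 1), "donor-group"), Selection((2,), "acceptor-group")


def generate_charged_dimer(
    charges: tuple[float, float],
    lj_params: tuple[tuple[float, float], tuple[float, float]],
    separation_series,
) -> tuple[Trajectory, Selection, Selection]:
    """Two single-atom groups at controlled separations along x.

    Closed-form energies are computable per frame:
    E_Coul = f q1 q2 / r and E_LJ = sqrt(C12_1 C12_2)/r^12 - sqrt(C6_1 C6_2)/r^6.
    """
    (c6a, c12a), (c6b, c12b) = lj_params
    atoms = [
        Atom(0, "A", "A", 1, "ION", "A", charge=charges[0], lj_c6=c6a, lj_c12=c12a),
        Atom(1, "B", "B", 2, "ION", "A", charge=charges[1], lj_c6=c6b, lj_c12=c12b),
    ]
    top = Topology(atoms)
    frames = [
        Frame(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]), time=t * 10.0)
        for t, r in enumerate(separation_series)
    ]
    return Trajectory(top, frames), Selection((0,), "A"), Selection((1,), "B")
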