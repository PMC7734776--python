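"""Domain types and I/O for loop-trajectory analysis.

Coordinates are stored in nanometres throughout; the PDB boundary converts
to/from Angstrom.  A :class:`Topology` couples the atom table (names,
residue numbering, partial charges, Lennard-Jones C6/C12 parameters and
hydrogen-bond roles) with a donor-hydrogen bond table; frames only carry
coordinates, a timestamp in ps and an optional system label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

NM_PER_ANGSTROM = 0.1

HBOND_ROLES = ("donor", "acceptor", "hydrogen", "none")


class TopologyError(ValueError):
    """Raised for inconsistent atom tables, bonds or sidecar files."""


class TrajectoryError(ValueError):
    """Raised for malformed or mutually inconsistent trajectory inputs."""


class SelectionError(ValueError):
    """Raised for invalid or empty atom selections."""


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    lj_c6: float = 0.0
    lj_c12: float = 0.0
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        if self.lj_c6 < 0 or self.lj_c12 < 0:
            raise TopologyError(
                f"atom {self.index} ({self.name}): LJ parameters must be >= 0"
            )
        if self.hbond_role not in HBOND_ROLES:
            raise TopologyError(
                f"atom {self.index} ({self.name}): unknown hbond role "
                f"{self.hbond_role!r}; expected one of {HBOND_ROLES}"
            )


@dataclass(frozen=True)
class BondTable:
    """Donor-hydrogen covalent bonds, as (donor_index, hydrogen_index) pairs."""

    pairs: tuple[tuple[int, int], ...] = ()

    def donor_of(self, hydrogen_index: int) -> int | None:
        for d, h in self.pairs:
            if h == hydrogen_index:
                return d
        return None


class Topology:
    """Immutable atom table shared by every frame of a trajectory."""

    def __init__(self, atoms: list[Atom], bonds: BondTable | None = None):
        atoms = list(atoms)
        if [a.index for a in atoms] != list(range(len(atoms))):
            raise TopologyError("atom indices must be contiguous from 0")
        bonds = bonds if bonds is not None else BondTable()
        seen_h: set[int] = set()
        for d, h in bonds.pairs:
            if not (0 <= d < len(atoms) and 0 <= h < len(atoms)):
                raise TopologyError(f"bond ({d},{h}) references missing atom")
            if h in seen_h:
                raise TopologyError(f"hydrogen {h} bound to more than one donor")
            seen_h.add(h)
        for a in atoms:
            if a.hbond_role == "hydrogen" and a.index not in seen_h:
                raise TopologyError(
                    f"hydrogen atom {a.index} ({a.name}) has no bonded donor"
                )
        self._atoms = tuple(atoms)
        self._bonds = bonds
        # dense arrays used by the energy/H-bond kernels
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.lj_c6 = np.array([a.lj_c6 for a in atoms], dtype=float)
        self.lj_c12 = np.array([a.lj_c12 for a in atoms], dtype=float)
        self.residue_numbers = np.array([a.residue_number for a in atoms], dtype=int)
        self.names = np.array([a.name for a in atoms])

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return self._atoms

    @property
    def bonds(self) -> BondTable:
        return self._bonds

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def donor_hydrogen_pairs(self) -> tuple[tuple[int, int], ...]:
        return self._bonds.pairs


@dataclass
class Frame:
    """One coordinate set (nm), with a timestamp in ps."""

    coordinates: np.ndarray
    time: float = 0.0
    system_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise TrajectoryError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def system_labels(self) -> list[str]:
        return [f.system_label for f in self.frames]


@dataclass(frozen=True)
class Selection:
    """Ordered, unique, ascending atom indices with a human-readable name."""

    indices: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise SelectionError(f"selection {self.name!r} is empty")
        if list(idx) != sorted(set(idx)):
            raise SelectionError(
                f"selection {self.name!r}: indices must be unique and ascending"
            )
        if idx[0] < 0:
            raise SelectionError(f"selection {self.name!r}: negative index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def validate(self, topology: Topology) -> None:
        if self.indices[-1] >= topology.n_atoms:
            raise SelectionError(
                f"selection {self.name!r}: index {self.indices[-1]} out of range "
                f"for topology with {topology.n_atoms} atoms"
            )


# ---------------------------------------------------------------------------
# selection expressions
# ---------------------------------------------------------------------------

def select_atoms(topology: Topology, query: str, name: str | None = None) -> Selection:
    """Resolve a selection expression against a topology.

    The grammar supports ``name <A> <B> ...`` (atom-name list),
    ``resid <a>-<b>`` / ``resid <a> <b> ...`` (residue numbers, author
    numbering, ranges inclusive) and conjunction with ``and``, e.g.
    ``"name CA and resid 25-149"``.  An empty result is an error, never a
    silently empty selection.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in [c.strip() for c in query.split(" and ")]:
        tokens = clause.split()
        if len(tokens) < 2:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
        keyword, args = tokens[0].lower(), tokens[1:]
        if keyword == "name":
            wanted = set(args)
            mask &= np.isin(topology.names, list(wanted))
        elif keyword == "resid":
            resmask = np.zeros(topology.n_atoms, dtype=bool)
            for tok in args:
                if "-" in tok[1:]:  # allow negative single numbers
                    lo_s, hi_s = tok.rsplit("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                    resmask |= (topology.residue_numbers >= lo) & (
                        topology.residue_numbers <= hi
                    )
                else:
                    resmask |= topology.residue_numbers == int(tok)
            mask &= resmask
        else:
            raise SelectionError(f"unknown selection keyword {keyword!r}")
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"selection {query!r} matched no atoms")
    return Selection(tuple(int(i) for i in indices), name=name or query)


# ---------------------------------------------------------------------------
# sidecar topology format
# ---------------------------------------------------------------------------
#
# One whitespace-delimited row per atom:
#   index name resnum resname charge c6 c12 role
# followed by an optional "BONDS" section of "donor_index hydrogen_index"
# rows.  '#' starts a comment.

def read_sidecar(path) -> Topology:
    atoms: dict[int, Atom] = {}
    bonds: list[tuple[int, int]] = []
    in_bonds = False
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper() == "BONDS":
                in_bonds = True
                continue
            parts = line.split()
            if in_bonds:
                if len(parts) != 2:
                    raise TopologyError(f"malformed BONDS row: {raw.rstrip()!r}")
                bonds.append((int(parts[0]), int(parts[1])))
            else:
                if len(parts) != 8:
                    raise TopologyError(f"malformed atom row: {raw.rstrip()!r}")
                idx = int(parts[0])
                name = parts[1]
                atoms[idx] = Atom(
                    index=idx,
                    name=name,
                    element=name[0],
                    residue_number=int(parts[2]),
                    residue_name=parts[3],
                    chain_id="A",
                    charge=float(parts[4]),
                    lj_c6=float(parts[5]),
                    lj_c12=float(parts[6]),
                    hbond_role=parts[7],
                )
    if not atoms:
        raise TopologyError(f"sidecar {path} contains no atoms")
    ordered = []
    for i in range(max(atoms) + 1):
        if i not in atoms:
            raise TopologyError(f"sidecar {path} is missing atom index {i}")
        ordered.append(atoms[i])
    return Topology(ordered, BondTable(tuple(bonds)))


def write_sidecar(topology: Topology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# index name resnum resname charge c6 c12 role\n")
        for a in topology.atoms:
            fh.write(
                f"{a.index} {a.name} {a.residue_number} {a.residue_name} "
                f"{a.charge:.6g} {a.lj_c6:.8g} {a.lj_c12:.8g} {a.hbond_role}\n"
            )
        if topology.bonds.pairs:
            fh.write("BONDS\n")
            for d, h in topology.bonds.pairs:
                fh.write(f"{d} {h}\n")


# ---------------------------------------------------------------------------
# multi-model PDB I/O
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path, sidecar) -> Trajectory:
    """Read a MODEL/ENDMDL PDB plus a sidecar topology into a Trajectory.

    Coordinates are converted from Angstrom to nm.  Every model must carry
    the same atoms in the same order; the sidecar must describe every atom.
    """
    topology = read_sidecar(sidecar)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    counts = [
        len(pdb.get_structure(model=m)) for m in range(1, n_models + 1)
    ]
    for m, c in enumerate(counts, start=1):
        if c != counts[0]:
            raise TrajectoryError(
                f"model {m} has {c} atoms but model 1 has {counts[0]}"
            )
    if counts[0] != topology.n_atoms:
        # name the first atom the sidecar/PDB disagree on
        raise TopologyError(
            f"sidecar describes {topology.n_atoms} atoms but PDB models have "
            f"{counts[0]}; first unmatched atom index {min(counts[0], topology.n_atoms)}"
        )
    frames = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        frames.append(
            Frame(coordinates=arr.coord * NM_PER_ANGSTROM, time=float(m - 1) * 10.0)
        )
    return Trajectory(topology, frames)


def write_multimodel_pdb(traj: Trajectory, selection: Selection, path) -> None:
    """Write the selected atoms of every frame as a multi-model PDB (Angstrom)."""
    selection.validate(traj.topology)
    if traj.n_frames == 0:
        raise TrajectoryError("cannot write an empty trajectory")
    idx = selection.as_array()
    n_sel = len(idx)
    template = struc.AtomArray(n_sel)
    for j, i in enumerate(idx):
        a = traj.topology.atoms[i]
        template.coord[j] = 0.0
        template.atom_name[j] = a.name
        template.element[j] = a.element
        template.res_id[j] = a.residue_number
        template.res_name[j] = a.residue_name
        template.chain_id[j] = a.chain_id
        template.hetero[j] = False
    stack = struc.AtomArrayStack(traj.n_frames, n_sel)
    for ann in ("atom_name", "element", "res_id", "res_name", "chain_id", "hetero"):
        stack.set_annotation(ann, template.get_annotation(ann))
    coords = traj.coordinate_array()[:, idx, :] / NM_PER_ANGSTROM
    stack.coord = np.asarray(coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# ensemble concatenation
# ---------------------------------------------------------------------------

def concatenate_trajectories(
    parts: list[tuple[Trajectory, str]],
    common_selection: Selection | None = None,
) -> Trajectory:
    """Timewise-concatenate trajectories from several systems into one ensemble.

    Each part's frames are tagged with its system label.  All parts must
    share one atom ordering; when topologies differ elsewhere the caller
    supplies the common selection used downstream and the concatenated
    trajectory is restricted to it.
    """
    if not parts:
        raise TrajectoryError("no trajectories to concatenate")

    def key(top: Topology, sel: Selection | None):
        idx = sel.as_array() if sel is not None else np.arange(top.n_atoms)
        return [(top.atoms[i].name, top.atoms[i].residue_number) for i in idx]

    ref_top = parts[0][0].topology
    ref_key = key(ref_top, common_selection)
    for traj, label in parts[1:]:
        if key(traj.topology, common_selection) != ref_key:
            raise TrajectoryError(
                f"system {label!r}: atom ordering incompatible with first part"
            )

    if common_selection is None:
        out_top = ref_top
        take = None
    else:
        idx = common_selection.as_array()
        atoms = []
        for j, i in enumerate(idx):
            atoms.append(replace(ref_top.atoms[i], index=j, chain_id="A"))
        out_top = Topology(atoms, BondTable())
        take = idx

    frames: list[Frame] = []
    for traj, label in parts:
        for f in traj.frames:
            coords = f.coordinates if take is None else f.coordinates[take]
            frames.append(Frame(coords.copy(), time=f.time, system_label=label))
    return Trajectory(out_top, frames)
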