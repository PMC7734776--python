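import numpy as np
import pytest

from loopconf.core import Atom, BondTable, Frame, Selection, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_plain_topology(n_atoms: int, residues_per_atom: int = 1) -> Topology:
    """n_atoms CA-like atoms, one residue each, no charges/LJ/H-bond roles."""
    atoms = [
        Atom(i, "CA", "C", i + 1, "GLY", "A")
        for i in range(n_atoms)
    ]
    return Topology(atoms, BondTable())


@pytest.fixture
def plain_topology():
    return make_plain_topology(5)


def trajectory_from_coords(coords: np.ndarray, labels=None) -> Trajectory:
    """Build a trajectory from an (n_frames, n_atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    top = make_plain_topology(coords.shape[1])
    frames = []
    for t in range(coords.shape[0]):
        lab = labels[t] if labels is not None else ""
        frames.append(Frame(coords[t], time=t * 10.0, system_label=lab))
    return Trajectory(top, frames)


def full_selection(n: int, name: str = "all") -> Selection:
    return Selection(tuple(range(n)), name)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
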