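"""Hydrogen-bond geometry and short-range non-bonded energies, checked
against brute-force oracles and closed forms."""

import numpy as np
import pytest

from loopconf.core import Atom, BondTable, Frame, Selection, Topology
from loopconf.interactions import (
    COULOMB_CONSTANT,
    InteractionError,
    energy_histogram,
    find_hbonds,
    hbond_count_series,
    hbond_histogram,
    pairwise_nonbonded_energy,
)
from loopconf.synthetic import generate_charged_dimer, generate_hbond_fixture


def hbond_topology():
    """Donor/H pair (group A) and one acceptor (group B)."""
    atoms = [
        Atom(0, "N", "N", 1, "GLY", "A", hbond_role="donor"),
        Atom(1, "HN", "H", 1, "GLY", "A", hbond_role="hydrogen"),
        Atom(2, "O", "O", 2, "GLY", "A", hbond_role="acceptor"),
    ]
    return Topology(atoms, BondTable(((0, 1),)))


def triple_frame(d_da, hydrogen_angle_deg):
    """Donor at origin, acceptor along +x at d_da, hydrogen 0.1 nm from the
    donor at the given angle off the donor->acceptor axis."""
    a = np.radians(hydrogen_angle_deg)
    return Frame(np.array([
        [0.0, 0.0, 0.0],
        [0.1 * np.cos(a), 0.1 * np.sin(a), 0.0],
        [d_da, 0.0, 0.0],
    ]))


GROUP_A = Selection((0, 1), "A")
GROUP_B = Selection((2,), "B")


class TestFindHbonds:
    def test_ideal_collinear_geometry_detected(self):
        bonds = find_hbonds(triple_frame(0.30, 0.0), hbond_topology(),
                            GROUP_A, GROUP_B)
        assert len(bonds) == 1
        hb = bonds[0]
        assert (hb.donor_index, hb.hydrogen_index, hb.acceptor_index) == (0, 1, 2)
        assert hb.distance == pytest.approx(0.30)
        assert hb.angle == pytest.approx(0.0, abs=1e-9)

    def test_distance_beyond_cutoff_rejected(self):
        assert find_hbonds(triple_frame(0.40, 0.0), hbond_topology(),
                           GROUP_A, GROUP_B) == []

    def test_bent_hydrogen_rejected(self):
        assert find_hbonds(triple_frame(0.30, 45.0), hbond_topology(),
                           GROUP_A, GROUP_B) == []

    def test_group_order_symmetric(self):
        frame = triple_frame(0.30, 10.0)
        top = hbond_topology()
        fwd = find_hbonds(frame, top, GROUP_A, GROUP_B)
        rev = find_hbonds(frame, top, GROUP_B, GROUP_A)
        assert fwd == rev

    def test_dha_convention_requires_near_linear_angle(self):
        # collinear D-H...A: DHA angle is 180 deg -> accepted under "DHA"
        frame = triple_frame(0.30, 0.0)
        top = hbond_topology()
        assert len(find_hbonds(frame, top, GROUP_A, GROUP_B,
                               angle_convention="DHA")) == 1
        # hydrogen 45 deg off-axis: DHA angle well below 150 -> rejected
        assert find_hbonds(triple_frame(0.30, 45.0), top, GROUP_A, GROUP_B,
                           angle_convention="DHA") == []

    def test_matches_brute_force_oracle_on_random_configurations(self):
        rng = np.random.default_rng(314)
        for _ in range(20):
            atoms, bonds = [], []
            coords = []
            # group A: 5 donor/H pairs; group B: 8 acceptors
            for k in range(5):
                i_n = len(atoms)
                atoms.append(Atom(i_n, "N", "N", k + 1, "GLY", "A",
                                  hbond_role="donor"))
                atoms.append(Atom(i_n + 1, "HN", "H", k + 1, "GLY", "A",
                                  hbond_role="hydrogen"))
                bonds.append((i_n, i_n + 1))
                base = rng.uniform(0, 0.8, size=3)
                coords.append(base)
                coords.append(base + rng.normal(scale=0.06, size=3))
            first_acc = len(atoms)
            for k in range(8):
                atoms.append(Atom(len(atoms), "O", "O", 10 + k, "GLY", "A",
                                  hbond_role="acceptor"))
                coords.append(rng.uniform(0, 0.8, size=3))
            top = Topology(atoms, BondTable(tuple(bonds)))
            frame = Frame(np.array(coords))
            sel_a = Selection(tuple(range(first_acc)), "A")
            sel_b = Selection(tuple(range(first_acc, len(atoms))), "B")
            got = {(b.donor_index, b.hydrogen_index, b.acceptor_index)
                   for b in find_hbonds(frame, top, sel_a, sel_b)}
            # brute-force triple loop
            expected = set()
            for d, h in bonds:
                for acc in range(first_acc, len(atoms)):
                    v_da = frame.coordinates[acc] - frame.coordinates[d]
                    v_dh = frame.coordinates[h] - frame.coordinates[d]
                    r = np.linalg.norm(v_da)
                    cosang = v_da @ v_dh / (np.linalg.norm(v_dh) * r)
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if r <= 0.35 and ang <= 30.0:
                        expected.add((d, h, acc))
            assert got == expected


class TestHbondSeries:
    def test_fixture_schedule_reproduced(self):
        schedule = [True, False, True, True, False]
        traj, sel_a, sel_b = generate_hbond_fixture(schedule)
        series = hbond_count_series(traj, sel_a, sel_b)
        np.testing.assert_array_equal(series, [1, 0, 1, 1, 0])

    def test_static_trajectory_constant_series(self):
        traj, sel_a, sel_b = generate_hbond_fixture([True] * 4)
        series = hbond_count_series(traj, sel_a, sel_b)
        np.testing.assert_array_equal(series, [1, 1, 1, 1])

    def test_long_random_schedule_equals_detector_output(self):
        rng = np.random.default_rng(1)
        schedule = rng.random(500) < 0.4
        traj, sel_a, sel_b = generate_hbond_fixture(schedule)
        series = hbond_count_series(traj, sel_a, sel_b)
        np.testing.assert_array_equal(series, schedule.astype(int))


class TestHbondHistogram:
    def test_direct_tally(self):
        assert hbond_histogram([0, 0, 4, 4, 4]) == {0: 2, 4: 3}

    def test_empty_series_rejected(self):
        with pytest.raises(InteractionError):
            hbond_histogram([])

    def test_conserves_frame_count(self, rng):
        series = rng.integers(0, 20, size=10000)
        hist = hbond_histogram(series)
        assert sum(hist.values()) == 10000
        values, counts = np.unique(series, return_counts=True)
        assert hist == {int(v): int(c) for v, c in zip(values, counts)}


def dimer_energy(q1, q2, lj1, lj2, r, cutoff=1.4):
    if r > cutoff:
        return 0.0, 0.0
    c6 = np.sqrt(lj1[0] * lj2[0])
    c12 = np.sqrt(lj1[1] * lj2[1])
    return COULOMB_CONSTANT * q1 * q2 / r, c12 / r ** 12 - c6 / r ** 6


class TestNonbondedEnergy:
    def test_unit_charge_pair_at_one_nm(self):
        traj, a, b = generate_charged_dimer((1.0, 1.0), ((0, 0), (0, 0)), [1.0])
        e = pairwise_nonbonded_energy(traj.frames[0], traj.topology, a, b)
        assert e.e_coulomb == pytest.approx(138.935458, abs=1e-6)
        assert e.e_lj == 0.0
        assert e.e_total == pytest.approx(e.e_coulomb + e.e_lj, abs=1e-9)

    def test_lj_zero_crossing(self):
        c6, c12 = 2.5e-3, 2.5e-6
        r0 = (c12 / c6) ** (1 / 6)
        traj, a, b = generate_charged_dimer((0.0, 0.0),
                                            ((c6, c12), (c6, c12)), [r0])
        e = pairwise_nonbonded_energy(traj.frames[0], traj.topology, a, b)
        assert e.e_lj == pytest.approx(0.0, abs=1e-9)

    def test_beyond_cutoff_is_zero(self):
        traj, a, b = generate_charged_dimer((1.0, -1.0), ((1e-3, 1e-6),) * 2, [1.5])
        e = pairwise_nonbonded_energy(traj.frames[0], traj.topology, a, b,
                                      cutoff=1.4)
        assert e.e_total == 0.0

    def test_overlapping_groups_rejected(self):
        traj, a, _ = generate_charged_dimer((1.0, 1.0), ((0, 0), (0, 0)), [1.0])
        with pytest.raises(InteractionError):
            pairwise_nonbonded_energy(traj.frames[0], traj.topology, a, a)

    def test_coincident_atoms_rejected(self):
        traj, a, b = generate_charged_dimer((1.0, 1.0), ((0, 0), (0, 0)), [0.0])
        with pytest.raises(InteractionError):
            pairwise_nonbonded_energy(traj.frames[0], traj.topology, a, b)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            n_a, n_b = 12, 15
            atoms = []
            for i in range(n_a + n_b):
                atoms.append(Atom(i, "X", "X", i + 1, "UNK", "A",
                                  charge=float(rng.uniform(-1, 1)),
                                  lj_c6=float(rng.uniform(0, 5e-3)),
                                  lj_c12=float(rng.uniform(0, 5e-6))))
            top = Topology(atoms)
            coords = rng.uniform(0, 1.6, size=(n_a + n_b, 3))
            frame = Frame(coords)
            sel_a = Selection(tuple(range(n_a)), "A")
            sel_b = Selection(tuple(range(n_a, n_a + n_b)), "B")
            got = pairwise_nonbonded_energy(frame, top, sel_a, sel_b, cutoff=1.4)
            e_coul = e_lj = 0.0
            for i in range(n_a):
                for j in range(n_a, n_a + n_b):
                    r = np.linalg.norm(coords[i] - coords[j])
                    if r > 1.4:
                        continue
                    e_coul += COULOMB_CONSTANT * atoms[i].charge * atoms[j].charge / r
                    c6 = np.sqrt(atoms[i].lj_c6 * atoms[j].lj_c6)
                    c12 = np.sqrt(atoms[i].lj_c12 * atoms[j].lj_c12)
                    e_lj += c12 / r ** 12 - c6 / r ** 6
            assert got.e_coulomb == pytest.approx(e_coul, rel=1e-9)
            assert got.e_lj == pytest.approx(e_lj, rel=1e-9)

    def test_group_swap_symmetry_and_charge_scaling(self, rng):
        n = 6
        atoms = [Atom(i, "X", "X", i + 1, "UNK", "A",
                      charge=float(rng.uniform(-1, 1)),
                      lj_c6=1e-3, lj_c12=1e-6) for i in range(2 * n)]
        top = Topology(atoms)
        frame = Frame(rng.uniform(0, 1.0, size=(2 * n, 3)))
        a = Selection(tuple(range(n)), "A")
        b = Selection(tuple(range(n, 2 * n)), "B")
        e_ab = pairwise_nonbonded_energy(frame, top, a, b)
        e_ba = pairwise_nonbonded_energy(frame, top, b, a)
        assert e_ba.e_coulomb == pytest.approx(e_ab.e_coulomb, rel=1e-12)
        assert e_ba.e_lj == pytest.approx(e_ab.e_lj, rel=1e-12)
        scaled = Topology([Atom(x.index, x.name, x.element, x.residue_number,
                                x.residue_name, x.chain_id, charge=3.0 * x.charge,
                                lj_c6=x.lj_c6, lj_c12=x.lj_c12) for x in atoms])
        e_scaled = pairwise_nonbonded_energy(frame, scaled, a, b)
        assert e_scaled.e_coulomb == pytest.approx(9.0 * e_ab.e_coulomb, rel=1e-9)
        assert e_scaled.e_lj == pytest.approx(e_ab.e_lj, rel=1e-9)

    def test_monotone_separation_series_monotone_coulomb(self):
        seps = [0.5, 0.7, 0.9, 1.1, 1.3]
        traj, a, b = generate_charged_dimer((1.0, 1.0), ((0, 0), (0, 0)), seps)
        energies = [pairwise_nonbonded_energy(f, traj.topology, a, b).e_coulomb
                    for f in traj.frames]
        assert all(x > y for x, y in zip(energies, energies[1:]))


class TestEnergyHistogram:
    def test_negative_values_bin_correctly(self):
        hist = energy_histogram([-950.0, -905.0], 100.0)
        assert hist == {-1000.0: 2}

    def test_edge_value_goes_to_higher_bin(self):
        hist = energy_histogram([-900.0, 100.0], 100.0)
        assert hist == {-900.0: 1, 100.0: 1}

    def test_conserves_counts_on_large_series(self, rng):
        series = rng.normal(-1000, 300, size=10000)
        hist = energy_histogram(series, 100.0)
        assert sum(hist.values()) == 10000
        ks, counts = np.unique(np.floor(series / 100.0), return_counts=True)
        assert hist == {float(k * 100.0): int(c) for k, c in zip(ks, counts)}

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(InteractionError):
            energy_histogram([1.0], 0.0)
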