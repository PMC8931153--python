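"""Hydrogen-bond/salt-bridge detection, rasters and occupancy statistics."""

import numpy as np
import pytest

from mechbond.interactions import (
    BondInstance,
    BondRaster,
    HBondCriteria,
    MissingHydrogensError,
    build_raster,
    detect_hbonds,
    detect_salt_bridges,
    nhb_series,
    occupancy,
)
from mechbond.structio import Atom, Frame, select
from mechbond.synthgen import BondSchedule, make_hbond_trajectory

from conftest import dha_frame


class TestDetectHBonds:
    @pytest.mark.parametrize(
        "a_pos, expected",
        [
            ((2.9, 0.0, 0.0), True),   # collinear, d = 2.9 Å
            ((3.6, 0.0, 0.0), False),  # distance fails
            ((2.1, 2.1, 0.0), False),  # d ≈ 2.97 Å but donor-vertex angle 45°
        ],
    )
    def test_geometric_criterion(self, a_pos, expected):
        frame = dha_frame((0, 0, 0), (1, 0, 0), a_pos)
        bonds, fallback = detect_hbonds(frame, [0, 1], [2])
        assert not fallback
        assert bool(bonds) is expected

    def test_hydrogen_vertex_convention(self):
        frame = dha_frame((0, 0, 0), (1, 0, 0), (2.9, 0, 0))
        crit = HBondCriteria(angle_convention="hydrogen-vertex")
        bonds, _ = detect_hbonds(frame, [0, 1], [2], crit)
        assert len(bonds) == 1

    def test_symmetric_in_group_order(self):
        frame = dha_frame((0, 0, 0), (1, 0, 0), (2.9, 0, 0))
        fwd, _ = detect_hbonds(frame, [0, 1], [2])
        rev, _ = detect_hbonds(frame, [2], [0, 1])
        assert fwd == rev

    def test_missing_hydrogens_error_or_fallback(self):
        atoms = [
            Atom(serial=1, name="N", element="N", resname="GLY", resid=1, chain="L"),
            Atom(serial=2, name="O", element="O", resname="GLY", resid=2, chain="R"),
        ]
        frame = Frame(atoms, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(MissingHydrogensError):
            detect_hbonds(frame, [0], [1], HBondCriteria(require_hydrogens=True))
        bonds, fallback = detect_hbonds(frame, [0], [1])
        assert fallback and len(bonds) == 1

    def test_brute_force_oracle_on_random_frames(self, rng):
        """Detection agrees with an independent all-pairs reimplementation."""
        crit = HBondCriteria()
        for _ in range(8):
            frame, ga, gb = _random_frame(rng, n_pairs=12, box=8.0)
            got = {
                (b.donor, b.acceptor)
                for b in detect_hbonds(frame, ga, gb, crit)[0]
            }
            assert got == _oracle_hbonds(frame, ga, gb, 3.5, 30.0)


def _random_frame(rng, n_pairs, box):
    """Random N/H donor and O acceptor atoms scattered in a box, two chains."""
    atoms, xyz = [], []
    serial = 1
    for k in range(n_pairs):
        chain = "L" if k % 2 == 0 else "R"
        n_pos = rng.uniform(0, box, 3)
        h_pos = n_pos + _random_unit(rng)  # 1 Å bond
        o_pos = rng.uniform(0, box, 3)
        for name, elem, pos in (("N", "N", n_pos), ("H", "H", h_pos), ("O", "O", o_pos)):
            atoms.append(
                Atom(serial=serial, name=name, element=elem, resname="GLY",
                     resid=k + 1, chain=chain)
            )
            xyz.append(pos)
            serial += 1
    frame = Frame(atoms, np.asarray(xyz))
    ga = [i for i, a in enumerate(atoms) if a.chain == "L"]
    gb = [i for i, a in enumerate(atoms) if a.chain == "R"]
    return frame, ga, gb


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _oracle_hbonds(frame, ga, gb, d_cut, ang_cut):
    """Plain-loop reference: backbone N(H) donors vs O acceptors."""
    found = set()
    for d_set, a_set in ((ga, gb), (gb, ga)):
        for d in d_set:
            if frame.atoms[d].name != "N":
                continue
            hs = [
                h for h in d_set
                if frame.atoms[h].name == "H"
                and frame.atoms[h].resid == frame.atoms[d].resid
                and np.linalg.norm(frame.coords[h] - frame.coords[d]) < 1.25
            ]
            for a in a_set:
                if frame.atoms[a].name != "O":
                    continue
                if np.linalg.norm(frame.coords[a] - frame.coords[d]) > d_cut:
                    continue
                for h in hs:
                    v1 = frame.coords[h] - frame.coords[d]
                    v2 = frame.coords[a] - frame.coords[d]
                    cos = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
                    if np.degrees(np.arccos(np.clip(cos, -1, 1))) <= ang_cut:
                        found.add(
                            (frame.atoms[d].atom_key, frame.atoms[a].atom_key)
                        )
                        break
    return found


class TestSaltBridges:
    def _frame(self, nz_x):
        atoms = [
            Atom(serial=1, name="OD1", element="O", resname="ASP", resid=1, chain="L"),
            Atom(serial=2, name="OD2", element="O", resname="ASP", resid=1, chain="L"),
            Atom(serial=3, name="NZ", element="N", resname="LYS", resid=2, chain="R"),
        ]
        return Frame(
            atoms, np.array([[0.0, 0, 0], [0.0, 1.2, 0], [nz_x, 0, 0]])
        )

    def test_within_cutoff(self):
        bridges = detect_salt_bridges(self._frame(3.9), [0, 1], [2])
        assert bridges == {(("L", 1), ("R", 2))}

    def test_outside_cutoff(self):
        assert not detect_salt_bridges(self._frame(4.3), [0, 1], [2])

    def test_two_oxygens_collapse_to_one_bridge(self):
        bridges = detect_salt_bridges(self._frame(2.0), [0, 1], [2])
        assert len(bridges) == 1


class TestRasterAndOccupancy:
    def _raster(self, schedules, n_frames, **kw):
        traj = make_hbond_trajectory(schedules, n_frames, **kw)
        return build_raster(traj, select(traj, "chain L"), select(traj, "chain R"))

    def test_single_bond_block_quarter(self):
        raster = self._raster([BondSchedule(target_occupancy=0.25)], 4)
        assert raster.states.shape == (1, 4)
        np.testing.assert_array_equal(raster.states[0], [True, False, False, False])

    def test_two_bonds_never_simultaneous(self):
        schedules = [
            BondSchedule(target_occupancy=0.5, pattern="block"),
            BondSchedule(target_occupancy=0.5, pattern="block", phase_frames=2),
        ]
        raster = self._raster(schedules, 4)
        counts = nhb_series(raster)
        assert set(counts) <= {0, 1}

    def test_static_bond_all_true(self):
        raster = self._raster([BondSchedule(target_occupancy=1.0)], 5)
        assert raster.states.all()

    def test_occupancy_fractions(self):
        states = np.zeros((2, 40), dtype=bool)
        states[0, :17] = True
        states[1, :] = True
        raster = BondRaster(
            [
                BondInstance(donor=("L", 1, "N"), acceptor=("R", 2, "O"), i=0, j=0),
                BondInstance(donor=("L", 3, "N"), acceptor=("R", 4, "O"), i=1, j=1),
            ],
            states,
            ligand_chains=frozenset("L"),
        )
        occ = occupancy(raster)
        assert occ["occupancy"].tolist() == [17 / 40, 1.0]

    def test_scheduled_occupancy_hits_target_within_quantisation(self):
        raster = self._raster([BondSchedule(target_occupancy=0.971)], 1000)
        assert abs(occupancy(raster)["occupancy"].iloc[0] - 0.971) <= 1 / 1000

    def test_nhb_counts_and_mass_balance(self):
        schedules = [
            BondSchedule(target_occupancy=w) for w in (0.25, 0.5, 0.75)
        ]
        raster = self._raster(schedules, 8)
        counts = nhb_series(raster)
        occ = occupancy(raster)
        assert counts.sum() == pytest.approx(
            (occ["occupancy"] * raster.n_frames).sum()
        )

    def test_empty_bond_set_counts_zero(self):
        raster = BondRaster([], np.zeros((0, 4), dtype=bool))
        np.testing.assert_array_equal(nhb_series(raster), np.zeros(4, dtype=int))
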