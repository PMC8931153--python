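"""Superposition, RMSD/RMSF, distances and angle descriptors."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mechbond.geomdesc import (
    DegenerateGeometryError,
    atom_distance_series,
    interaxis_angle_series,
    kabsch_superpose,
    rmsd_series,
    rmsf,
    segment_axis,
    turn_angle_series,
)
from mechbond.structio import Atom, Frame, Trajectory
from mechbond.synthgen import make_ca_chain, make_rigid_jitter_trajectory


class TestKabsch:
    def test_identical_sets(self):
        pts = make_ca_chain(6).coords
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_A == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_pure_rotation(self):
        pts = make_ca_chain(6).coords
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        res = kabsch_superpose(pts, pts @ R.T)
        assert res.rmsd_A == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, R, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numerical_optimum_with_displaced_point(self):
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mob = ref.copy()
        mob[3] += (1.0, 0.0, 0.0)
        res = kabsch_superpose(mob, ref)

        def cost(params):
            R = Rotation.from_euler("xyz", params[:3]).as_matrix()
            moved = mob @ R.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in (np.zeros(6), np.array([0.1, -0.1, 0.2, 0.3, 0, 0]))
        )
        assert res.rmsd_A == pytest.approx(best, abs=1e-6)

    def test_degenerate_fit_set_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_and_rigid_motion_are_zero(self):
        base = make_ca_chain(8)
        rots = [
            Rotation.from_euler("y", 10 * k, degrees=True).as_matrix()
            for k in range(5)
        ]
        trans = [np.array([0.0, 0.5 * k, 0]) for k in range(5)]
        traj = make_rigid_jitter_trajectory(base, 5, rotations=rots, translations=trans)
        series = rmsd_series(traj, np.arange(base.n_atoms))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_jittered_matches_expectation(self, rng):
        """With per-atom isotropic jitter σ, frame RMSD ≈ its Monte-Carlo mean."""
        base = make_ca_chain(40)
        sigma = 0.3
        traj = make_rigid_jitter_trajectory(base, 200, jitter_sigma_A=sigma, seed=7)
        series = rmsd_series(traj, np.arange(base.n_atoms))
        # simulation oracle: fresh jittered frames against the trajectory's
        # own (jittered) reference frame, superposed the same way
        ref = traj.frames[0].coords
        mc = []
        for _ in range(200):
            noisy = base.coords + rng.normal(0, sigma, base.coords.shape)
            sup = kabsch_superpose(noisy, ref)
            moved = noisy @ sup.rotation.T + sup.translation
            mc.append(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
        assert series.values[1:].mean() == pytest.approx(np.mean(mc), rel=0.05)

    def test_after_fit_not_worse_than_before(self):
        base = make_ca_chain(10)
        traj = make_rigid_jitter_trajectory(
            base, 10, translations=[np.array([k, 0.0, 0]) for k in range(10)],
            jitter_sigma_A=0.2, seed=3,
        )
        fitted = rmsd_series(traj, np.arange(base.n_atoms)).values
        raw = np.array(
            [
                np.sqrt(np.mean(np.sum((fr.coords - traj.frames[0].coords) ** 2, axis=1)))
                for fr in traj.frames
            ]
        )
        assert np.all(fitted <= raw + 1e-9)


class TestRmsf:
    def test_static_is_zero(self):
        base = make_ca_chain(5)
        traj = make_rigid_jitter_trajectory(base, 4)
        np.testing.assert_allclose(rmsf(traj, np.arange(5)), 0.0, atol=1e-12)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        base = make_ca_chain(30)
        sigma = 0.5
        traj = make_rigid_jitter_trajectory(base, 2000, jitter_sigma_A=sigma, seed=11)
        vals = rmsf(traj, np.arange(base.n_atoms))
        assert vals.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_mobile_atom_dominates(self):
        base = make_ca_chain(20)
        coords = [base.coords.copy() for _ in range(10)]
        for k, c in enumerate(coords):
            c[7, 2] += 1.0 if k % 2 else -1.0
        traj = Trajectory([Frame(list(base.atoms), c) for c in coords])
        vals = rmsf(traj, np.arange(20))
        assert np.argmax(vals) == 7
        others = np.delete(vals, 7)
        assert others.max() < 0.15 * vals[7]

    def test_invariant_under_global_rigid_motion(self):
        base = make_ca_chain(12)
        traj = make_rigid_jitter_trajectory(base, 50, jitter_sigma_A=0.3, seed=4)
        ref_vals = rmsf(traj, np.arange(12))
        R = Rotation.from_euler("xyz", [0.3, -0.7, 1.1]).as_matrix()
        moved = Trajectory(
            [Frame(list(f.atoms), f.coords @ R.T + np.array([5.0, -2, 1])) for f in traj.frames]
        )
        np.testing.assert_allclose(rmsf(moved, np.arange(12)), ref_vals, atol=1e-9)

    def test_single_frame_rejected(self):
        traj = make_rigid_jitter_trajectory(make_ca_chain(4), 1)
        with pytest.raises(ValueError):
            rmsf(traj, np.arange(4))


class TestDistances:
    def test_three_four_five(self):
        base = make_ca_chain(2)
        coords = np.array([[0.0, 0, 0], [3, 4, 0]])
        traj = Trajectory([Frame(list(base.atoms), coords)])
        assert atom_distance_series(traj, 0, 1).values[0] == pytest.approx(5.0)

    def test_coincident_is_zero(self):
        base = make_ca_chain(2)
        traj = Trajectory([Frame(list(base.atoms), np.zeros((2, 3)))])
        assert atom_distance_series(traj, 0, 1).values[0] == 0.0

    def test_interpolating_trajectory_endpoints(self):
        """A separation ramping 14 → 17 Å reports those endpoint distances."""
        base = make_ca_chain(2)
        frames = []
        for d in np.linspace(14.0, 17.0, 7):
            frames.append(Frame(list(base.atoms), np.array([[0.0, 0, 0], [d, 0, 0]])))
        series = atom_distance_series(Trajectory(frames), 0, 1)
        assert series.values[0] == pytest.approx(14.0)
        assert series.values[-1] == pytest.approx(17.0)

    def test_missing_atom_errors(self):
        base = make_ca_chain(2)
        traj = Trajectory([Frame(list(base.atoms), np.zeros((2, 3)))])
        with pytest.raises(IndexError):
            atom_distance_series(traj, 0, 5)


class TestAxesAndAngles:
    def test_points_on_x_axis(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        np.testing.assert_allclose(segment_axis(pts), (1, 0, 0), atol=1e-12)

    def test_ideal_helix_axis_along_z(self):
        n = 36  # ten full turns at 100°/residue, phases balance exactly
        t = np.arange(n) * np.radians(100.0)
        pts = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
        axis = segment_axis(pts)
        angle = np.degrees(np.arccos(abs(axis @ np.array([0, 0, 1.0]))))
        assert angle < 1.0

    def test_planar_isotropic_scatter_rejected(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(400)])
        with pytest.raises(DegenerateGeometryError):
            segment_axis(pts)

    def _segment_traj(self, dir_b):
        """Two 4-point straight segments: one along x, one along dir_b."""
        dir_b = np.asarray(dir_b, dtype=float)
        atoms = [
            Atom(serial=k + 1, name="CA", element="C", resname="GLY",
                 resid=k + 1, chain="A" if k < 4 else "B")
            for k in range(8)
        ]
        steps = np.arange(4.0)[:, None]
        coords = np.vstack(
            [steps * np.array([3.8, 0, 0]), np.array([0, 50.0, 0]) + steps * dir_b * 3.8]
        )
        # tiny transverse perturbation keeps the fit sets non-collinear
        coords = coords + 0.001 * np.array([[0, (k % 2), ((k + 1) % 2)] for k in range(8)])
        return Trajectory([Frame(atoms, coords)])

    @pytest.mark.parametrize(
        "dir_b, expected",
        [
            ((np.cos(np.radians(30)), np.sin(np.radians(30)), 0), 30.0),
            ((1, 0, 0), 0.0),
            ((-1, 0, 0), 0.0),  # antiparallel folds into [0°, 90°]
        ],
    )
    def test_interaxis_angles(self, dir_b, expected):
        traj = self._segment_traj(dir_b)
        series = interaxis_angle_series(traj, np.arange(4), np.arange(4, 8))
        assert series.values[0] == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.array([2.0, 0, 0]), 0.0),    # collinear
            (np.array([0, 2.0, 0]), 90.0),   # perpendicular
            (np.array([2.0, 2.0, 0]), 45.0),
        ],
    )
    def test_turn_angle(self, p, expected):
        base = make_ca_chain(4)
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 5, 5], [5.0, 5, 5] + p / 2])
        traj = Trajectory([Frame(list(base.atoms), coords)])
        series = turn_angle_series(traj, (0, 1), (2, 3))
        assert series.values[0] == pytest.approx(expected, abs=1e-9)

    def test_coincident_line_endpoints_rejected(self):
        base = make_ca_chain(4)
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        traj = Trajectory([Frame(list(base.atoms), coords)])
        with pytest.raises(DegenerateGeometryError):
            turn_angle_series(traj, (0, 1), (2, 3))
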