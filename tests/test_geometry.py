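"""Geometric observables: superposition, RMSD/RMSF, COM distances, hinge
angle and solvent-accessible surface area."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from alloscope import geometry
from alloscope.errors import DegenerateGeometryError, InsufficientDataError
from _utils import full_selection, make_topology, make_trajectory, random_rigid_transform


def ca_cloud(n_atoms, rng, chain="A"):
    topo = make_topology([("CA", "C", chain, i + 1, "ALA") for i in range(n_atoms)])
    coords = rng.uniform(-10, 10, size=(n_atoms, 3))
    return topo, coords


class TestSuperpose:
    def test_pure_translation_recovered_exactly(self, rng):
        topo, ref = ca_cloud(8, rng)
        frames = np.stack([ref, ref + np.array([3.0, -2.0, 7.0])])
        traj = make_trajectory(topo, frames)
        fitted = geometry.superpose(traj, full_selection(topo), 0)
        np.testing.assert_allclose(fitted.coordinates[1], ref, atol=1e-10)

    def test_rigid_rotation_recovered(self, rng):
        topo, ref = ca_cloud(8, rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        frames = np.stack([ref, rot.apply(ref)])
        traj = make_trajectory(topo, frames)
        fitted = geometry.superpose(traj, full_selection(topo), 0)
        rmsd = geometry.rmsd_timeseries(fitted, full_selection(topo), 0)
        assert rmsd.values[1] < 1e-10

    def test_idempotent(self, rng):
        topo, ref = ca_cloud(10, rng)
        frames = ref[None] + rng.normal(scale=1.0, size=(5, 10, 3))
        traj = make_trajectory(topo, frames)
        once = geometry.superpose(traj, full_selection(topo), 0)
        twice = geometry.superpose(once, full_selection(topo), 0)
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-10

    def test_matches_independent_qcp_oracle(self, rng):
        """Post-fit RMSD equals MDAnalysis' quaternion (QCP) superposition."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        topo, ref = ca_cloud(12, rng)
        sel = full_selection(topo)
        for _ in range(5):
            noisy = ref + rng.normal(scale=1.5, size=ref.shape)
            rot, trans = random_rigid_transform(rng)
            frame = noisy @ rot.T + trans
            traj = make_trajectory(topo, np.stack([ref, frame]))
            ours = geometry.rmsd_timeseries(
                geometry.superpose(traj, sel, 0), sel, 0
            ).values[1]
            oracle = mda_rmsd(frame, ref, superposition=True)
            assert abs(ours - oracle) < 1e-8

    def test_collinear_fit_set_rejected(self):
        topo = make_topology([("CA", "C", "A", i + 1, "ALA") for i in range(4)])
        line = np.array([[float(i), 0.0, 0.0] for i in range(4)])
        traj = make_trajectory(topo, np.stack([line, line]))
        with pytest.raises(DegenerateGeometryError):
            geometry.superpose(traj, full_selection(topo), 0)


class TestRMSD:
    def test_reference_frame_is_zero(self, rng):
        topo, ref = ca_cloud(6, rng)
        traj = make_trajectory(topo, np.stack([ref, ref + 1.0]))
        assert geometry.rmsd_timeseries(traj, full_selection(topo), 0).values[0] == 0.0

    def test_single_displaced_atom_analytic(self):
        topo = make_topology([("CA", "C", "A", i + 1, "ALA") for i in range(4)])
        ref = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
        moved = ref.copy()
        moved[0, 0] += 2.0  # one atom displaced by 2 A among N=4
        traj = make_trajectory(topo, np.stack([ref, moved]))
        value = geometry.rmsd_timeseries(traj, full_selection(topo), 0).values[1]
        assert value == pytest.approx(np.sqrt(2.0**2 / 4.0))  # = 1.0 A

    def test_matches_direct_formula(self, rng):
        topo, ref = ca_cloud(10, rng)
        frame = ref + rng.normal(scale=2.0, size=ref.shape)
        traj = make_trajectory(topo, np.stack([ref, frame]))
        value = geometry.rmsd_timeseries(traj, full_selection(topo), 0).values[1]
        oracle = np.sqrt(np.mean(np.sum((frame - ref) ** 2, axis=1)))
        assert value == pytest.approx(oracle, abs=1e-12)


class TestRMSF:
    def test_static_trajectory_is_zero(self, rng):
        topo, ref = ca_cloud(5, rng)
        traj = make_trajectory(topo, np.repeat(ref[None], 10, axis=0))
        profile = geometry.rmsf_profile(traj, full_selection(topo))
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self, rng):
        """iid per-axis Gaussian displacements: RMSF -> sigma*sqrt(3)."""
        sigma = 0.5
        topo, ref = ca_cloud(10, rng)
        frames = ref[None] + rng.normal(scale=sigma, size=(100_000, 10, 3))
        traj = make_trajectory(topo, frames, dt_ns=0.01)
        profile = geometry.rmsf_profile(traj, full_selection(topo))
        expected = sigma * np.sqrt(3.0)
        assert np.all(np.abs(profile.values - expected) / expected < 0.02)

    def test_single_frame_rejected(self, rng):
        topo, ref = ca_cloud(5, rng)
        traj = make_trajectory(topo, ref[None])
        with pytest.raises(InsufficientDataError):
            geometry.rmsf_profile(traj, full_selection(topo))


class TestComDistance:
    def two_groups(self, coords_a, coords_b):
        atoms = [("CA", "C", "A", 1, "ALA")] * len(coords_a) + [
            ("CA", "C", "B", 1, "ALA")
        ] * len(coords_b)
        # one residue per chain group
        topo = make_topology(
            [("CA", "C", "A", i + 1, "ALA") for i in range(len(coords_a))]
            + [("CA", "C", "B", i + 1, "ALA") for i in range(len(coords_b))]
        )
        coords = np.vstack([coords_a, coords_b])
        from alloscope.structure import ResidueSelection

        sel_a = ResidueSelection(np.arange(len(coords_a)), "A", np.arange(len(coords_a)))
        sel_b = ResidueSelection(
            np.arange(len(coords_a), len(coords)),
            "B",
            np.arange(len(coords_a), len(coords)),
        )
        return topo, coords, sel_a, sel_b

    def test_two_single_atoms(self):
        topo, coords, sel_a, sel_b = self.two_groups(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 10.0]])
        )
        traj = make_trajectory(topo, np.stack([coords, coords]))
        series = geometry.com_distance_timeseries(traj, sel_a, sel_b)
        np.testing.assert_allclose(series.values, 10.0)

    def test_symmetric_pair_reduces_to_centroid(self):
        # equal-mass pair straddling the origin vs a point at (d, 0, 0)
        d = 7.0
        topo, coords, sel_a, sel_b = self.two_groups(
            np.array([[0.0, 3.0, 0.0], [0.0, -3.0, 0.0]]), np.array([[d, 0.0, 0.0]])
        )
        traj = make_trajectory(topo, coords[None])
        series = geometry.com_distance_timeseries(traj, sel_a, sel_b)
        assert series.values[0] == pytest.approx(d)

    def test_invariant_under_global_rigid_motion(self, rng):
        topo, coords, sel_a, sel_b = self.two_groups(
            rng.uniform(-5, 5, (4, 3)), rng.uniform(5, 15, (3, 3))
        )
        frames = [coords]
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            frames.append(coords @ rot.T + trans)
        traj = make_trajectory(topo, np.stack(frames))
        series = geometry.com_distance_timeseries(traj, sel_a, sel_b)
        np.testing.assert_allclose(series.values, series.values[0], atol=1e-9)

    def test_overlapping_selections_warn(self, rng):
        topo, coords, sel_a, _ = self.two_groups(
            rng.uniform(-5, 5, (4, 3)), rng.uniform(5, 15, (3, 3))
        )
        traj = make_trajectory(topo, coords[None])
        with pytest.warns(UserWarning, match="overlap"):
            geometry.com_distance_timeseries(traj, sel_a, sel_a)


class TestHingeAngle:
    def build(self, apex, arm_a, arm_b):
        topo = make_topology(
            [("CA", "C", "A", 1, "ALA"), ("CA", "C", "A", 2, "ALA"), ("CA", "C", "A", 3, "ALA")]
        )
        from alloscope.structure import ResidueSelection

        sels = [
            ResidueSelection(np.array([i]), name, np.array([i]))
            for i, name in enumerate(["apex", "a", "b"])
        ]
        coords = np.array([apex, arm_a, arm_b], dtype=float)[None]
        return make_trajectory(topo, coords), sels

    def test_collinear_is_180(self):
        traj, (apex, a, b) = self.build([1, 0, 0], [0, 0, 0], [2, 0, 0])
        series = geometry.hinge_angle_timeseries(traj, apex, a, b)
        assert series.series.values[0] == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        traj, (apex, a, b) = self.build([0, 0, 0], [1, 0, 0], [0, 1, 0])
        series = geometry.hinge_angle_timeseries(traj, apex, a, b)
        assert series.series.values[0] == pytest.approx(90.0)

    def test_multi_atom_selections_reduce_to_com_oracle(self, rng):
        """Angle over multi-atom selections equals the single-point angle of
        the precomputed centroids."""
        from alloscope.structure import ResidueSelection

        topo = make_topology([("CA", "C", "A", i + 1, "ALA") for i in range(9)])
        coords = rng.uniform(-10, 10, (9, 3))
        traj = make_trajectory(topo, coords[None])
        groups = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        sels = [
            ResidueSelection(g, name, g) for g, name in zip(groups, ["apex", "a", "b"])
        ]
        value = geometry.hinge_angle_timeseries(traj, *sels).series.values[0]
        coms = [coords[g].mean(axis=0) for g in groups]
        v1, v2 = coms[1] - coms[0], coms[2] - coms[0]
        oracle = np.degrees(
            np.arccos(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert value == pytest.approx(oracle, abs=1e-10)

    def test_coincident_coms_rejected(self):
        traj, (apex, a, b) = self.build([0, 0, 0], [0, 0, 0], [0, 1, 0])
        with pytest.raises(DegenerateGeometryError):
            geometry.hinge_angle_timeseries(traj, apex, a, b)


class TestSASA:
    def test_isolated_atom_sphere_area(self):
        topo = make_topology([("O", "O", "A", 1, "HOH")])
        traj = make_trajectory(topo, np.zeros((1, 1, 3)))
        probe = 1.4
        series = geometry.sasa_timeseries(traj, full_selection(topo), probe)
        r = geometry.BONDI_RADII["O"] + probe
        assert series.values[0] == pytest.approx(4 * np.pi * r**2, rel=0.01)

    def test_fully_buried_atom_is_zero(self):
        # central atom enclosed by a tight shell of neighbours
        shell = geometry._sphere_points(60) * 2.2
        atoms = [("C", "C", "A", 1, "LIG")] + [
            ("C", "C", "A", i + 2, "LIG") for i in range(len(shell))
        ]
        topo = make_topology(atoms)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])[None]
        traj = make_trajectory(topo, coords)
        from alloscope.structure import ResidueSelection

        central = ResidueSelection(np.array([0]), "central", np.array([0]))
        series = geometry.sasa_timeseries(traj, central, 1.4)
        assert series.values[0] < 1e-6

    def test_two_sphere_analytic_overlap(self):
        """Two overlapping atoms vs the closed-form two-sphere area."""
        probe = 1.4
        r1 = geometry.BONDI_RADII["C"] + probe
        r2 = geometry.BONDI_RADII["O"] + probe
        d = 2.0
        topo = make_topology([("C", "C", "A", 1, "LIG"), ("O", "O", "A", 2, "LIG")])
        coords = np.array([[[0.0, 0.0, 0.0], [d, 0.0, 0.0]]])
        traj = make_trajectory(topo, coords)
        series = geometry.sasa_timeseries(traj, full_selection(topo), probe)
        # spherical-cap geometry: cap boundary at x = (d^2 + r1^2 - r2^2)/(2d)
        x1 = (d**2 + r1**2 - r2**2) / (2 * d)
        x2 = (d**2 + r2**2 - r1**2) / (2 * d)
        area1 = 2 * np.pi * r1 * (r1 + x1)
        area2 = 2 * np.pi * r2 * (r2 + x2)
        assert series.values[0] == pytest.approx(area1 + area2, rel=0.02)

    def test_unknown_element_radius_reported(self):
        topo = make_topology(
            [("XX", "X", "A", 1, "LIG")], masses={"X": 10.0}
        )
        traj = make_trajectory(topo, np.zeros((1, 1, 3)))
        with pytest.raises(geometry.ParameterizationError, match="X"):
            geometry.sasa_timeseries(traj, full_selection(topo))
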