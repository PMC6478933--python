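"""Generator determinism, analytic ground truth and pipeline closure."""

import json

import numpy as np
import pytest

from conftest import ANALYTIC_R, CYL_LENGTH, CYL_RADIUS
from poreclog import channel as ch
from poreclog import conductance as cond
from poreclog import occupancy as occ
from poreclog import synthetic as syn
from poreclog import trajio
from poreclog.errors import PlacementError, ValidationError


class TestGeometry:
    def test_cylinder_analytic_area_is_pi_r_squared(self):
        system = syn.make_pore(syn.cylinder_pore(radius=5.0, length=50.0))
        np.testing.assert_allclose(system.analytic_area([1.0, 25.0, 49.0]),
                                   np.pi * 25.0)

    def test_hourglass_minimum_at_waist(self):
        system = syn.make_pore(syn.hourglass_pore(radius=8.0, radius_waist=3.0, length=50.0))
        zs = np.linspace(0.5, 49.5, 99)
        areas = system.analytic_area(zs)
        assert areas.min() == pytest.approx(np.pi * 9.0, rel=1e-2)
        assert np.argmin(areas) == 49  # mid-pore
        r_entry = system.geometry.radius_at(zs[0])
        assert areas[0] == pytest.approx(np.pi * r_entry**2, rel=1e-12)
        assert areas[0] > areas[10] > areas[40]

    def test_pocketed_profile_equals_plain_cylinder(self):
        pocketed = syn.make_pore(syn.pocketed_pore())
        plain = syn.make_pore(syn.cylinder_pore())
        zs = np.arange(0.5, 50.0)
        np.testing.assert_allclose(pocketed.analytic_area(zs), plain.analytic_area(zs))

    def test_wall_spheres_tile_without_large_gaps(self):
        system = syn.make_pore(syn.cylinder_pore(radius=5.0, length=20.0))
        w = system.geometry.wall_sphere_radius
        # every wall atom has a neighbour closer than its own radius
        from scipy.spatial import cKDTree

        tree = cKDTree(system.wall_coords)
        dists, _ = tree.query(system.wall_coords, k=2)
        assert dists[:, 1].max() <= w

    def test_too_small_channel_is_degenerate(self):
        with pytest.raises(ValidationError):
            syn.make_pore(syn.cylinder_pore(radius=0.5, length=10.0, wall_sphere_radius=1.0))


class TestObstruction:
    def test_annulus_area_on_obstructed_slices(self):
        system = syn.make_pore(syn.cylinder_pore())
        obstructed = syn.insert_obstruction(system, bead_radius=3.0, z_lo=10.0, z_hi=30.0)
        assert obstructed.analytic_area([20.0])[0] == pytest.approx(np.pi * (25.0 - 9.0))
        assert obstructed.analytic_area([5.0])[0] == pytest.approx(np.pi * 25.0)

    def test_zero_radius_bead_chain_changes_nothing(self):
        system = syn.make_pore(syn.cylinder_pore())
        obstructed = syn.insert_obstruction(system, bead_radius=0.0)
        zs = np.arange(0.5, 50.0)
        np.testing.assert_allclose(obstructed.analytic_area(zs), system.analytic_area(zs))

    def test_full_radius_bead_warns_and_blocks(self):
        system = syn.make_pore(syn.cylinder_pore())
        with pytest.warns(UserWarning, match="fully blocked"):
            blocked = syn.insert_obstruction(system, bead_radius=5.0)
        assert blocked.analytic_area([25.0])[0] == 0.0
        assert blocked.analytic_resistance() == np.inf


class TestTrajectoryGeneration:
    def test_fixed_seed_reproduces_coordinates_bitwise(self, cylinder_system):
        spec = syn.ElectrolyteSpec(n_water=20, n_k=2, n_cl=2, diffusion=3.0, seed=99)
        t1 = syn.make_trajectory(cylinder_system, spec, n_frames=10)
        t2 = syn.make_trajectory(cylinder_system, spec, n_frames=10)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_static_spec_gives_static_frames(self, cylinder_system):
        spec = syn.ElectrolyteSpec(n_water=10, seed=1)
        traj = syn.make_trajectory(cylinder_system, spec, n_frames=5)
        np.testing.assert_array_equal(traj.coords[0], traj.coords[-1])

    def test_particles_stay_inside_accessible_region(self, cylinder_system):
        spec = syn.ElectrolyteSpec(n_water=30, n_k=3, n_cl=3, diffusion=4.0, seed=6)
        traj = syn.make_trajectory(cylinder_system, spec, n_frames=20)
        idx = trajio.select(traj, trajio.ELECTROLYTE)
        pts = traj.coords[:, idx, :].reshape(-1, 3)
        assert cylinder_system.accessible(pts).all()

    def test_overfilled_channel_rejected(self):
        small = syn.make_pore(syn.cylinder_pore(radius=2.0, length=10.0))
        with pytest.raises(PlacementError):
            syn.make_trajectory(small, syn.ElectrolyteSpec(n_water=5000, seed=0), n_frames=2)

    def test_ground_truth_sidecar_round_trips(self, tmp_path, cylinder_system):
        spec = syn.ElectrolyteSpec(n_k=5, n_cl=5, drift_k=0.025, drift_cl=-0.025, seed=0)
        syn.write_ground_truth(cylinder_system, spec, tmp_path / "gt.json")
        payload = json.loads((tmp_path / "gt.json").read_text())
        assert payload["shape"] == "CYLINDER"
        np.testing.assert_allclose(payload["analytic_area"],
                                   np.pi * CYL_RADIUS**2, rtol=1e-12)
        assert payload["electrolyte"]["expected_drift_current_nA"] == pytest.approx(
            syn.expected_drift_current(cylinder_system, spec))


class TestPipelineClosure:
    def test_sampled_cylinder_recovers_analytic_area_profile(
        self, cylinder_system, sampled_cylinder
    ):
        """occupancy → channel → area on the sampled cylinder reproduces
        A(z) = πr² within 10% at 1 Å cells and 4% at 0.5 Å cells.

        The first and last water-diameter of the analysis window are
        excluded: slices there lose part of their VdW smearing mass to the
        window edge, an artifact of any finite analysis window rather than
        of the pipeline."""
        idx = trajio.select(sampled_cylinder, trajio.ELECTROLYTE)
        analytic = np.pi * CYL_RADIUS**2
        edge = 2.0 * 1.4  # one water diameter
        for cell, tol in ((1.0, 0.10), (0.5, 0.04)):
            grid = cylinder_system.default_grid(cell)
            avg = occ.trajectory_occupancy(sampled_cylinder, idx, grid)
            norm, _ = occ.normalize_bulk(avg, cylinder_system.bulk_region(grid))
            prof = cond.area_profile(ch.through_channel(norm), z_range=(0.0, CYL_LENGTH))
            interior = (prof.z > edge) & (prof.z < CYL_LENGTH - edge)
            rel = np.abs(prof.area[interior] - analytic) / analytic
            assert rel.max() < tol

    def test_pocket_kept_by_flood_fill_but_removed_by_monotone_filter(self):
        """The monotone-z filter is what excludes the reentrant pocket: a
        plain 3D flood fill keeps it and inflates the pocket slices' area."""
        system = syn.make_pore(syn.pocketed_pore())
        grid = system.default_grid(1.0)
        m = syn.geometry_occupancy(system, grid)
        filtered = ch.through_channel(m)
        naive = ch.apply_mask(m, ch.flood_fill_accessibility(m))
        pocket = system.geometry.pocket
        mid = int((pocket.z_lo + pocket.z_hi) / 2 - pocket.neck_height)
        a_filtered = cond.area_profile(filtered).area[mid]
        a_naive = cond.area_profile(naive).area[mid]
        assert a_naive > a_filtered + 20.0
        assert a_filtered == pytest.approx(np.pi * CYL_RADIUS**2, rel=0.05)

    def test_drift_current_ground_truth_with_diffusion(self):
        """With diffusion on top of drift the measured mean current matches
        Σq·v/L_z within 3 standard errors."""
        system = syn.make_pore(syn.cylinder_pore(radius=5.0, length=100.0))
        spec = syn.ElectrolyteSpec(n_k=15, n_cl=15, drift_k=0.02, drift_cl=-0.02,
                                   diffusion=2.0, seed=21)
        traj = syn.make_trajectory(system, spec, n_frames=251)
        from poreclog import current as cur

        idx = trajio.select(traj, {"ION_K", "ION_CL"})
        m = cur.mean_current(cur.displacement_current(traj, idx), block=400.0)
        expected = syn.expected_drift_current(system, spec)
        assert m.n_windows >= 200
        assert abs(m.mean - expected) < 3.0 * max(m.se, 1e-12)
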