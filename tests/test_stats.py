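"""Amino-acid tables, replica statistics, correlations and trajectory
summaries."""

import numpy as np
import pytest

from oracles import pearson_fit_bruteforce
from poreclog import stats as st
from poreclog import synthetic as syn
from poreclog import trajio
from poreclog.errors import DegenerateInputError, LookupTableError, ValidationError
from poreclog.stats import HydropathyClass
from poreclog.trajio import AtomMeta, Species, Trajectory


class TestAminoAcidTable:
    @pytest.mark.parametrize(
        "code,volume",
        [("A", 88.6), ("W", 227.8), ("Q", 143.9), ("F", 189.9)],
    )
    def test_vdw_volumes_of_the_four_reference_residues(self, code, volume):
        assert st.aa_lookup(code).vdw_volume == volume

    def test_table_has_all_twenty_standard_residues(self):
        table = st.aa_table()
        assert len(table) == 20
        assert set("ACDEFGHIKLMNPQRSTVWY") == set(table.index)
        assert (table[["vdw_volume", "apparent_volume", "asa"]] > 0).all().all()

    def test_classes_partition_with_standard_charge_assignment(self):
        table = st.aa_table()
        by_class = {c.value: set(table.index[table.hclass == c.value]) for c in HydropathyClass}
        assert by_class["POSITIVE"] == {"R", "K"}
        assert by_class["NEGATIVE"] == {"D", "E"}
        assert "H" in by_class["POLAR"]
        union = set().union(*by_class.values())
        assert union == set(table.index)
        assert sum(len(v) for v in by_class.values()) == 20

    def test_histidine_class_is_configurable(self):
        assert st.aa_lookup("H", his_class="POSITIVE").hclass is HydropathyClass.POSITIVE
        assert st.aa_lookup("H").hclass is HydropathyClass.POLAR

    def test_unknown_code_raises(self):
        with pytest.raises(LookupTableError):
            st.aa_lookup("B")


class TestReplicaStats:
    def test_sem_of_one_two_three(self):
        rs = st.replica_stats([1.0, 2.0, 3.0])
        assert rs.mean == 2.0
        assert rs.sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_single_replica_flagged_with_zero_sem(self):
        with pytest.warns(UserWarning, match="n=1"):
            rs = st.replica_stats([5.0])
        assert rs.mean == 5.0 and rs.sem == 0.0 and rs.single_replica

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            st.replica_stats([])


class TestPearsonFit:
    def test_perfect_line_recovered_exactly(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = st.pearson_and_fit(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([0.0, 1.0, 2.0])
        assert st.pearson_and_fit(x, -x).r == pytest.approx(-1.0)

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateInputError):
            st.pearson_and_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_bruteforce_covariance_to_1e12(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=30)
            y = 0.7 * x + rng.normal(size=30)
            res = st.pearson_and_fit(x, y)
            r, slope, intercept = pearson_fit_bruteforce(x, y)
            assert abs(res.r - r) < 1e-12
            assert abs(res.slope - slope) < 1e-12
            assert abs(res.intercept - intercept) < 1e-12


class TestClassContrast:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        res = st.class_contrast({"HYDROPHOBIC": a, "POLAR": a})
        assert res.mean_difference == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_five_sigma_shift_is_significant(self):
        rng = np.random.default_rng(1)
        res = st.class_contrast({
            "HYDROPHOBIC": rng.normal(5.0, 1.0, 10),
            "POLAR": rng.normal(0.0, 1.0, 10),
        })
        assert res.p_value < 0.01
        assert res.mean_difference > 3.0

    def test_singleton_class_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="excluded"):
            res = st.class_contrast({
                "HYDROPHOBIC": rng.normal(size=5),
                "POLAR": rng.normal(size=5),
                "POSITIVE": [1.0],
            })
        assert res.excluded == ["POSITIVE"]


class TestTrajectorySummaries:
    def _static_traj(self, positions: np.ndarray, species_rows) -> Trajectory:
        meta = [AtomMeta(i, n, r, s, q, rad)
                for i, (n, r, s, q, rad) in enumerate(species_rows)]
        coords = np.tile(positions, (3, 1, 1))
        return Trajectory(topology=meta, coords=coords,
                          boxes=np.tile([40.0, 40.0, 60.0], (3, 1)),
                          times=np.array([0.0, 40.0, 80.0]), frame_interval=40.0)

    def test_ion_water_ratio_of_static_fixture(self):
        rows = ([("OW", "SOL", Species.WATER, 0.0, 1.4)] * 100
                + [("K", "ION", Species.ION_K, 1.0, 1.5)] * 3
                + [("CL", "ION", Species.ION_CL, -1.0, 1.8)] * 3)
        pos = np.zeros((106, 3))
        pos[:, 2] = 30.0  # everything inside the region
        traj = self._static_traj(pos, rows)
        assert st.ion_water_ratio(traj, (0.0, 60.0)) == pytest.approx(0.06)

    def test_no_ions_gives_zero_ratio(self):
        rows = [("OW", "SOL", Species.WATER, 0.0, 1.4)] * 10
        pos = np.zeros((10, 3)); pos[:, 2] = 30.0
        assert st.ion_water_ratio(self._static_traj(pos, rows), (0.0, 60.0)) == 0.0

    def test_region_without_water_degenerate(self):
        rows = [("OW", "SOL", Species.WATER, 0.0, 1.4)] * 10
        pos = np.zeros((10, 3)); pos[:, 2] = 55.0
        with pytest.raises(DegenerateInputError):
            st.ion_water_ratio(self._static_traj(pos, rows), (0.0, 10.0))

    def test_two_unit_masses_two_angstrom_apart_have_rg_one(self):
        rows = [("C1", "PEP", Species.PEPTIDE, 0.0, 1.7)] * 2
        pos = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 12.0]])
        _, rg = st.radius_of_gyration(self._static_traj(pos, rows), [0, 1])
        np.testing.assert_allclose(rg, 1.0)

    def test_rigid_translation_leaves_rg_constant(self):
        rng = np.random.default_rng(3)
        rows = [("C1", "PEP", Species.PEPTIDE, 0.0, 1.7)] * 8
        base = rng.random((8, 3)) * 5
        coords = np.stack([base + np.array([0, 0, dz]) for dz in (0.0, 3.0, 7.0)])
        meta = [AtomMeta(i, n, r, s, q, rad) for i, (n, r, s, q, rad) in enumerate(rows)]
        traj = Trajectory(topology=meta, coords=coords,
                          boxes=np.tile([40.0, 40.0, 60.0], (3, 1)),
                          times=np.array([0.0, 40.0, 80.0]), frame_interval=40.0)
        _, rg = st.radius_of_gyration(traj, list(range(8)))
        np.testing.assert_allclose(rg, rg[0], rtol=1e-12)

    def test_relaxation_time_of_exponential_series(self):
        """A noisy exponential approach with τ = 10 ns settles within ±5% of
        its plateau at a time of the order of τ."""
        rng = np.random.default_rng(12)
        t = np.arange(0.0, 64_000.0, 40.0)  # ps
        tau = 10_000.0
        series = 10.0 + 5.0 * np.exp(-t / tau) + rng.normal(0, 0.05, t.size)
        estimate = st.relaxation_time(t, series, band=0.05)
        # analytic settling time of the noise-free series: τ ln(10) ≈ 23 ns
        assert 0.5 * tau <= estimate <= 3.5 * tau

    def test_smd_displacement_printed_protocol(self):
        assert st.smd_displacement(0.025, 17.0) == pytest.approx(425.0)

    def test_smd_displacement_unit_conversion(self):
        assert st.smd_displacement(1.0, 1.0) == pytest.approx(1000.0)

    def test_smd_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            st.smd_displacement(0.0, 17.0)


class TestEndToEndCorrelation:
    def test_clogging_tracks_drift_blockage_across_obstructions(self, cylinder_system):
        """Desk-scale analogue of the clogging-vs-blockage correlation: for
        obstructions of growing radius, b from the analytic-area route and
        the drift-current blockage are almost perfectly correlated."""
        from conftest import analytic_profile
        from poreclog import conductance as cond

        p0 = analytic_profile(cylinder_system)
        radii = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5]
        b_vals, blockages = [], []
        system0 = cylinder_system
        v0 = np.pi * system0.geometry.radius**2 * system0.geometry.length
        for rb in radii:
            obstructed = syn.insert_obstruction(system0, bead_radius=rb)
            b_vals.append(cond.clogging_from_profiles(
                analytic_profile(obstructed), p0).b)
            v = v0 * (1 - rb**2 / system0.geometry.radius**2)
            n_ions = max(2, int(round(syn.ION_DENSITY_2M * v)))
            spec = syn.ElectrolyteSpec(n_k=n_ions, n_cl=n_ions,
                                       drift_k=0.025, drift_cl=-0.025, seed=7)
            traj = syn.make_trajectory(obstructed, spec, n_frames=5)
            idx = trajio.select(traj, {Species.ION_K, Species.ION_CL})
            from poreclog import current as cur
            i_mean = cur.mean_current(cur.displacement_current(traj, idx)).mean
            spec0 = syn.ElectrolyteSpec(
                n_k=max(2, int(round(syn.ION_DENSITY_2M * v0))),
                n_cl=max(2, int(round(syn.ION_DENSITY_2M * v0))),
                drift_k=0.025, drift_cl=-0.025, seed=7)
            traj0 = syn.make_trajectory(system0, spec0, n_frames=5)
            i0 = cur.mean_current(cur.displacement_current(
                traj0, trajio.select(traj0, {Species.ION_K, Species.ION_CL}))).mean
            blockages.append(cur.blockage(i_mean, i0).blockage)
        res = st.pearson_and_fit(b_vals, blockages)
        assert res.r > 0.9
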