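"""Trajectory statistics: superposition, RMSD, RMSF, Rg, RDF, pair monitoring.

MDAnalysis provides the independent cross-check for the RMSD path; all
closed-form expectations (sigma*sqrt(3) RMSF, ideal-gas g(r)=1, cube
radius of gyration) are derived analytically in the test bodies.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tspc4 import (
    AnalysisError,
    SelectionError,
    Trajectory,
    cc_pair_distances,
    kabsch_superpose,
    loop_contact_fraction,
    radius_of_gyration_series,
    rdf,
    rmsd_series,
    rmsf_per_residue,
    time_average_rmsd,
)
from tspc4.io import Atom, Structure
from tspc4.stats import TimeSeries
from tspc4.synthetic import (
    FluctuationSpec,
    make_gaussian_trajectory,
    make_ideal_gas_frames,
    make_pair_drift_trajectory,
)


def _static_traj(structure, n_frames=3):
    return Trajectory(
        topology=structure,
        frames=np.repeat(structure.coordinates[None], n_frames, axis=0),
    )


def _point_structure(coords, masses=None):
    coords = np.asarray(coords, dtype=float)
    masses = masses if masses is not None else np.ones(len(coords))
    atoms = tuple(
        Atom(name="X", element="X", residue_index=i + 1, residue_name="UNK",
             mass=float(m))
        for i, m in enumerate(masses)
    )
    return Structure(atoms=atoms, coordinates=coords)


class TestKabsch:
    def test_exact_rigid_motion_inverted(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(30, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        tr = kabsch_superpose(mobile, ref)
        assert not tr.degenerate
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)
        np.testing.assert_allclose(tr.apply(mobile), ref, atol=1e-10)

    def test_identity_for_identical_clouds(self):
        coords = np.random.default_rng(1).normal(size=(10, 3))
        tr = kabsch_superpose(coords, coords)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_fit_never_worse_than_raw(self, seed):
        """Best-fit RMSD <= raw RMSD on random perturbed clouds."""
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(50, 3)) * 3
        mobile = ref + rng.normal(size=(50, 3)) * 0.4
        mobile = mobile @ Rotation.random(rng=seed).as_matrix().T + rng.normal(size=3)
        raw = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
        fitted = np.sqrt(
            np.mean(np.sum((kabsch_superpose(mobile, ref).apply(mobile) - ref) ** 2,
                           axis=1))
        )
        assert fitted <= raw + 1e-12

    def test_collinear_input_flagged_translation_only(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        tr = kabsch_superpose(line, line + np.array([0.0, 2.0, 0.0]))
        assert tr.degenerate
        np.testing.assert_allclose(tr.apply(line), line + [0.0, 2.0, 0.0], atol=1e-10)


class TestRmsd:
    def test_reference_frame_gives_zero(self, toy_structure, whole_sel):
        traj = _static_traj(toy_structure)
        series = rmsd_series(traj, whole_sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_pure_translation_is_five_unfitted_zero_fitted(
        self, toy_structure, whole_sel
    ):
        moved = toy_structure.coordinates + np.array([3.0, 4.0, 0.0])
        traj = Trajectory(
            topology=toy_structure,
            frames=np.stack([toy_structure.coordinates, moved]),
        )
        unfitted = rmsd_series(traj, whole_sel, fit=False)
        assert unfitted.values[1] == pytest.approx(5.0)
        fitted = rmsd_series(traj, whole_sel, fit=True)
        assert fitted.values[1] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_hand_computation(self):
        """Atoms displaced (+1,0,0)/(-1,0,0): centered, no rotation gain -> 1 A."""
        s = _point_structure([[-5.0, 0, 0], [5.0, 0, 0]])
        frame1 = s.coordinates + np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        traj = Trajectory(topology=s, frames=np.stack([s.coordinates, frame1]))
        series = rmsd_series(traj, np.arange(2), fit=False)
        assert series.values[1] == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, toy_structure, whole_sel, ccct3_regions):
        """Applying one rigid motion to every frame leaves fitted RMSD unchanged."""
        traj = make_gaussian_trajectory(
            toy_structure, FluctuationSpec(sigma=0.7, seed=5), 40,
            regions=ccct3_regions,
        )
        base = rmsd_series(traj, whole_sel).values
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = Trajectory(
            topology=toy_structure,
            frames=traj.frames @ rot.T + np.array([5.0, -3.0, 8.0]),
        )
        np.testing.assert_allclose(
            rmsd_series(moved, whole_sel).values, base, atol=1e-6
        )

    def test_matches_mdanalysis_oracle(self, toy_structure, whole_sel, ccct3_regions):
        """Independent check of the best-fit RMSD against MDAnalysis."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        traj = make_gaussian_trajectory(
            toy_structure, FluctuationSpec(sigma=0.9, seed=6), 20,
            regions=ccct3_regions,
        )
        ours = rmsd_series(traj, whole_sel).values
        ref = traj.frames[0]
        theirs = [
            mda_rmsd(frame, ref, center=True, superposition=True)
            for frame in traj.frames
        ]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_whole_msd_decomposes_over_regions(
        self, toy_structure, ccct3_regions, whole_sel
    ):
        """With a common fit, whole mean-square deviation is the atom-count
        weighted mix of core and loop mean-square deviations."""
        from tspc4 import AtomSelection, select_atoms

        traj = make_gaussian_trajectory(
            toy_structure, FluctuationSpec(sigma=0.6, seed=7), 25,
            regions=ccct3_regions,
        )
        core = select_atoms(toy_structure, AtomSelection("core"), ccct3_regions)
        loop = select_atoms(toy_structure, AtomSelection("loop"), ccct3_regions)
        whole_v = rmsd_series(traj, whole_sel, fit_selection=whole_sel).values
        core_v = rmsd_series(traj, core, fit_selection=whole_sel).values
        loop_v = rmsd_series(traj, loop, fit_selection=whole_sel).values
        mix = (core.size * core_v**2 + loop.size * loop_v**2) / whole_sel.size
        np.testing.assert_allclose(whole_v**2, mix, atol=1e-10)

    def test_empty_selection_rejected(self, toy_structure):
        traj = _static_traj(toy_structure)
        with pytest.raises(SelectionError):
            rmsd_series(traj, np.array([], dtype=int))


class TestTimeAverage:
    def test_constant_series(self):
        s = TimeSeries(times=np.arange(4.0), values=np.full(4, 2.0))
        assert time_average_rmsd(s) == pytest.approx(2.0)

    def test_burn_in_drops_early_frames(self):
        s = TimeSeries(times=np.arange(4.0), values=np.array([1.0, 2.0, 3.0, 4.0]))
        assert time_average_rmsd(s, burn_in=1.0) == pytest.approx(3.0)

    def test_burn_in_beyond_series_rejected(self):
        s = TimeSeries(times=np.arange(4.0), values=np.ones(4))
        with pytest.raises(AnalysisError):
            time_average_rmsd(s, burn_in=10.0)

    def test_matches_brute_force_mean(self, toy_structure, whole_sel, ccct3_regions):
        traj = make_gaussian_trajectory(
            toy_structure, FluctuationSpec(sigma=0.5, seed=8), 50,
            regions=ccct3_regions,
        )
        series = rmsd_series(traj, whole_sel)
        assert time_average_rmsd(series) == pytest.approx(series.values.mean())


class TestRmsf:
    def test_static_trajectory_zero(self, toy_structure, whole_sel):
        traj = _static_traj(toy_structure, n_frames=5)
        rmsf = rmsf_per_residue(traj, whole_sel)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf.values())

    def test_isotropic_gaussian_recovers_sigma_sqrt3(
        self, toy_structure, whole_sel
    ):
        """Unfitted RMSF of i.i.d. noise with per-coordinate sd 0.5 A is
        0.5*sqrt(3) ~ 0.866 A."""
        traj = make_gaussian_trajectory(
            toy_structure, FluctuationSpec(sigma=0.5, seed=9), 10_000,
            noisy_first_frame=True,
        )
        rmsf = rmsf_per_residue(traj, whole_sel, fit=False)
        expected = 0.5 * np.sqrt(3.0)
        vals = np.array(list(rmsf.values()))
        assert np.all(np.abs(vals / expected - 1.0) < 0.03)

    def test_loop_exceeds_core_when_constructed_so(
        self, toy_structure, whole_sel, ccct3_regions
    ):
        """Loops given 3x the core amplitude fluctuate more, residue by residue
        (the canonical per-residue flexibility profile)."""
        traj = make_gaussian_trajectory(
            toy_structure,
            FluctuationSpec(sigma={"core": 0.3, "loop": 0.9}, seed=10),
            2000,
            regions=ccct3_regions,
        )
        rmsf = rmsf_per_residue(traj, whole_sel, fit=False)
        core_max = max(
            rmsf[r] for r in ccct3_regions.residues("core")
        )
        assert all(
            rmsf[r] > core_max for r in ccct3_regions.residues("loop")
        )


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        s = _point_structure([[1.0, 1.0, 1.0]])
        series = radius_of_gyration_series(_static_traj(s), np.array([0]))
        assert series.values[0] == pytest.approx(0.0)

    def test_two_equal_masses(self):
        s = _point_structure([[-3.0, 0, 0], [3.0, 0, 0]])
        series = radius_of_gyration_series(_static_traj(s), np.arange(2))
        assert series.values[0] == pytest.approx(3.0)

    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)], dtype=float
        )
        s = _point_structure(corners)
        series = radius_of_gyration_series(_static_traj(s), np.arange(8))
        assert series.values[0] == pytest.approx(np.sqrt(3.0))

    def test_mass_weighting_changes_result(self):
        s = _point_structure([[-3.0, 0, 0], [3.0, 0, 0]], masses=[1.0, 3.0])
        heavy = radius_of_gyration_series(
            _static_traj(s), np.arange(2), mass_weighted=True
        ).values[0]
        uniform = radius_of_gyration_series(
            _static_traj(s), np.arange(2), mass_weighted=False
        ).values[0]
        assert heavy != pytest.approx(uniform)


class TestRdf:
    def test_ideal_gas_is_flat_unity(self):
        """g(r) of uniform points at the reference density is 1 everywhere."""
        gas = make_ideal_gas_frames(density=0.03, box=20.0, n_frames=50, seed=2)
        idx = np.arange(gas.n_atoms)
        profile = rdf(gas, idx, idx, dr=0.1, max_r=10.0, density=0.03, box=20.0)
        assert float(np.mean(np.abs(profile.g_of_r - 1.0))) < 0.05

    def test_counts_conserved_between_histogram_and_distances(self):
        gas = make_ideal_gas_frames(density=0.03, box=20.0, n_frames=2, seed=3)
        idx = np.arange(gas.n_atoms)
        profile = rdf(gas, idx, idx, dr=0.5, max_r=10.0, box=20.0)
        # brute-force count of min-image pair distances below max_r
        expected = 0
        for frame in gas.frames:
            diff = frame[:, None, :] - frame[None, :, :]
            diff -= 20.0 * np.round(diff / 20.0)
            d = np.sqrt((diff**2).sum(axis=2))
            np.fill_diagonal(d, np.inf)
            expected += int((d < 10.0).sum())
        assert int(profile.counts.sum()) == expected

    def test_fixed_pair_gives_sharp_peak_at_separation(self):
        """Two atoms held at 2.0 A: all histogram mass lands in that bin."""
        s = _point_structure([[0.0, 0, 0], [2.0, 0, 0]])
        traj = _static_traj(s, n_frames=4)
        profile = rdf(traj, np.array([0]), np.array([1]), dr=0.1, max_r=5.0)
        peak_bin = int(np.argmax(profile.counts))
        assert abs(profile.bin_centers[peak_bin] - 2.0) <= 0.05 + 1e-9
        assert profile.counts.sum() == profile.counts[peak_bin]

    def test_literal_normalization_differs_from_shell(self):
        s = _point_structure([[0.0, 0, 0], [2.0, 0, 0]])
        traj = _static_traj(s, n_frames=1)
        shell = rdf(traj, np.array([0]), np.array([1]), normalization="shell")
        literal = rdf(traj, np.array([0]), np.array([1]), normalization="literal")
        assert not np.allclose(shell.g_of_r, literal.g_of_r)

    def test_out_of_range_warns_all_zero(self):
        s = _point_structure([[0.0, 0, 0], [50.0, 0, 0]])
        traj = _static_traj(s, n_frames=1)
        with pytest.warns(UserWarning):
            profile = rdf(traj, np.array([0]), np.array([1]), max_r=5.0)
        assert np.all(profile.g_of_r == 0.0)


class TestPairDistances:
    def test_static_native_all_maintained(
        self, toy_structure, ccct3, ccct3_topology
    ):
        traj = _static_traj(toy_structure, n_frames=10)
        report = cc_pair_distances(traj, ccct3_topology, ccct3)
        assert set(report.status) == {"maintained"}
        for s in report.series:
            np.testing.assert_allclose(s.values, 2.8, atol=1e-9)

    def test_drifting_pair_is_the_only_disruption(
        self, toy_structure, ccct3, ccct3_topology
    ):
        traj = make_pair_drift_trajectory(
            toy_structure, ccct3_topology, ccct3,
            drifting_pair="C2b:C4b", drift_distance=8.0, drift_fraction=0.6,
            n_frames=100,
        )
        report = cc_pair_distances(
            traj, ccct3_topology, ccct3, cutoff=3.5, disruption_fraction=0.5
        )
        assert report.disrupted_pairs() == ("C2b:C4b",)

    def test_disruption_raises_core_rmsd(
        self, toy_structure, ccct3, ccct3_topology, ccct3_regions
    ):
        """A single opened pair increases the time-averaged core-region RMSD
        relative to the all-maintained control."""
        from tspc4 import AtomSelection, select_atoms

        core = select_atoms(toy_structure, AtomSelection("core"), ccct3_regions)
        control = _static_traj(toy_structure, n_frames=100)
        drift = make_pair_drift_trajectory(
            toy_structure, ccct3_topology, ccct3,
            drifting_pair="C2c:C4c", drift_distance=8.0, drift_fraction=0.6,
            n_frames=100,
        )
        avg_control = time_average_rmsd(rmsd_series(control, core))
        avg_drift = time_average_rmsd(rmsd_series(drift, core))
        assert avg_drift > avg_control

    def test_missing_n3_bead_rejected(self, ccct3, ccct3_topology):
        bare = _point_structure(np.zeros((21, 3)) + np.arange(21)[:, None])
        traj = _static_traj(bare)
        with pytest.raises(AnalysisError):
            cc_pair_distances(traj, ccct3_topology, ccct3)


class TestLoopContacts:
    def _three_loop_structure(self, ccct3, separation):
        from tspc4.synthetic import make_toy_imotif_structure

        s = make_toy_imotif_structure(ccct3)
        coords = s.coordinates.copy()
        loop3 = [15, 16, 17]  # 0-based residues of loop3
        loop1 = [3, 4, 5]
        coords[loop3] = coords[loop1] + np.array([separation, 0.0, 0.0])
        return Structure(atoms=s.atoms, coordinates=coords)

    def test_far_apart_never_in_contact(self, ccct3, ccct3_regions):
        s = self._three_loop_structure(ccct3, separation=30.0)
        frac = loop_contact_fraction(_static_traj(s, 10), ccct3_regions)
        assert frac == 0.0

    def test_overlapping_always_in_contact(self, ccct3, ccct3_regions):
        s = self._three_loop_structure(ccct3, separation=0.5)
        frac = loop_contact_fraction(_static_traj(s, 10), ccct3_regions)
        assert frac == 1.0

    def test_constructed_forty_percent_contact(self, ccct3, ccct3_regions):
        near = self._three_loop_structure(ccct3, separation=0.5)
        far = self._three_loop_structure(ccct3, separation=30.0)
        frames = np.concatenate([
            np.repeat(near.coordinates[None], 4, axis=0),
            np.repeat(far.coordinates[None], 6, axis=0),
        ])
        traj = Trajectory(topology=near, frames=frames)
        assert loop_contact_fraction(traj, ccct3_regions) == pytest.approx(0.4)

    def test_unknown_loop_label_rejected(self, ccct3, ccct3_regions, toy_structure):
        with pytest.raises(SelectionError):
            loop_contact_fraction(
                _static_traj(toy_structure), ccct3_regions, loop_a="loop9"
            )
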