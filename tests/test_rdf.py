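import numpy as np
import pytest

from halodesign import fixtures as fx
from halodesign.rdf import (
    RdfCurve,
    Trajectory,
    TrajectoryError,
    compare_association,
    find_peaks,
    merge_runs,
    rdf_min_distance,
    rdf_site,
    read_frames,
    read_xyz,
    residence_events,
    write_xyz,
)


def make_curve(g, bin_width=0.1):
    edges = np.arange(0, (len(g) + 0.5) * bin_width, bin_width)[: len(g) + 1]
    return RdfCurve(bin_edges=edges, g=np.asarray(g, dtype=float), reference="raw", frames_used=1)


class TestTrajectoryIO:
    def test_one_frame_pdb(self, tmp_path):
        pdb = tmp_path / "t.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3 NA    NA A 101       9.000   0.000   0.000  1.00  0.00          NA\n"
        )
        traj = read_frames(pdb, format="pdb", selections={"protein": "protein", "ions": "NA"})
        assert traj.n_frames == 1 and traj.n_atoms == 3
        assert list(traj.group("ions")) == [2]
        assert list(traj.group("protein")) == [0, 1]

    def test_multimodel_pdb(self, tmp_path):
        blocks = []
        for m in range(5):
            blocks.append(
                f"MODEL     {m + 1}\n"
                f"ATOM      1  CA  GLY A   1    {float(m):8.3f}   0.000   0.000  1.00  0.00           C\n"
                "ENDMDL\n"
            )
        pdb = tmp_path / "t.pdb"
        pdb.write_text("".join(blocks))
        traj = read_frames(pdb, format="pdb")
        assert traj.n_frames == 5
        assert traj.frames[3, 0, 0] == pytest.approx(3.0)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        pdb = tmp_path / "t.pdb"
        pdb.write_text(
            "MODEL     1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL     2\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        with pytest.raises(TrajectoryError, match="frame 1"):
            read_frames(pdb, format="pdb")

    def test_xyz_round_trip(self, tmp_path, shell_trajectory):
        names = fx.trajectory_atom_names(shell_trajectory)
        path = tmp_path / "t.xyz"
        write_xyz(path, names, shell_trajectory.frames)
        names2, frames2 = read_xyz(path)
        assert names2 == names
        np.testing.assert_allclose(frames2, shell_trajectory.frames, atol=1e-6)


class TestMinDistanceCurve:
    def test_uniform_ions_give_flat_unit_curve(self, uniform_trajectory):
        curve = rdf_min_distance(uniform_trajectory, bin_width=0.5, r_max=12.0, seed=5)
        # null case: real ions drawn from the same uniform law as the MC
        # reference; each occupied bin should sit within 3 standard errors of 1
        n_real = 30 * uniform_trajectory.n_frames
        counts = curve.g  # ratio estimate; recompute SE from occupancy
        centers = curve.bin_centers
        mask = (centers > 2.0) & (centers < 10.0)
        # aggregate check: mean of g over the populated window near 1
        assert abs(curve.g[mask].mean() - 1.0) < 3.0 / np.sqrt(n_real / mask.sum())

    def test_planted_distance_occupies_single_bin(self):
        traj = fx.make_ion_trajectory(
            np.zeros((1, 3)), n_ions=10, n_frames=20, shells=[(2.2, 1.0)], seed=3
        )
        # bin width chosen so 2.2 A falls strictly inside one bin
        curve = rdf_min_distance(traj, reference="raw", bin_width=0.08)
        occupied = curve.bin_centers[curve.g > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(2.2, abs=0.08)

    def test_ion_count_invariance_in_expectation(self):
        curves = []
        for n_ions in (15, 30):
            traj = fx.make_ion_trajectory(
                np.zeros((1, 3)), n_ions=n_ions, n_frames=80,
                shells=[(3.0, 0.5)], uniform_weight=0.5, seed=21,
            )
            curves.append(rdf_min_distance(traj, bin_width=0.5, r_max=8.0, seed=9))
        a, b = curves
        peak_bin = np.argmax(a.g)
        assert b.g[peak_bin] == pytest.approx(a.g[peak_bin], rel=0.25)

    def test_binning_validation(self, uniform_trajectory):
        with pytest.raises(ValueError, match="r_max"):
            rdf_min_distance(uniform_trajectory, bin_width=2.0, r_max=1.0)


class TestSiteRdf:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(12)
        box = 20.0
        n_ions, n_frames = 200, 40
        frames = np.empty((n_frames, n_ions + 1, 3))
        frames[:, 0] = box / 2
        frames[:, 1:] = rng.uniform(0, box, size=(n_frames, n_ions, 3))
        traj = Trajectory(
            frames=frames,
            groups={"site": np.array([0]), "ions": np.arange(1, n_ions + 1)},
            box=np.full(3, box),
        )
        curve = rdf_site(traj, site="site", bin_width=0.5, r_max=8.0)
        mask = curve.bin_centers > 1.0
        assert abs(curve.g[mask].mean() - 1.0) < 0.05

    def test_fixed_shell_peaks_and_integrates_to_count(self):
        rng = np.random.default_rng(4)
        box, radius, n_ions, n_frames = 30.0, 4.0, 12, 50
        frames = np.empty((n_frames, n_ions + 1, 3))
        frames[:, 0] = box / 2
        for f in range(n_frames):
            directions = rng.normal(size=(n_ions, 3))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            frames[f, 1:] = box / 2 + radius * directions
        traj = Trajectory(
            frames=frames,
            groups={"site": np.array([0]), "ions": np.arange(1, n_ions + 1)},
            box=np.full(3, box),
        )
        curve = rdf_site(traj, site="site", bin_width=0.1, r_max=8.0)
        peaks = find_peaks(curve, min_height=1.0)
        assert any(abs(p - radius) <= 0.1 for p in peaks)
        # integral of rho * g * 4 pi r^2 dr over the peak recovers the count
        rho = n_ions / box**3
        shell_counts = curve.g * rho * 4 * np.pi * curve.bin_centers**2 * 0.1
        assert shell_counts.sum() == pytest.approx(n_ions, rel=0.01)

    def test_zero_ions_zero_curve(self):
        frames = np.zeros((3, 1, 3))
        traj = Trajectory(
            frames=frames,
            groups={"site": np.array([0]), "ions": np.array([], dtype=int)},
            box=np.full(3, 10.0),
        )
        curve = rdf_site(traj, site="site", bin_width=0.5, r_max=4.0)
        assert not curve.g.any()

    def test_missing_box_rejected(self):
        traj = Trajectory(frames=np.zeros((1, 2, 3)), groups={"site": np.array([0]), "ions": np.array([1])})
        with pytest.raises(ValueError, match="box"):
            rdf_site(traj, site="site")


class TestPeaks:
    def test_bimodal_recovered(self):
        centers = np.arange(0.05, 6.0, 0.1)
        g = 3.0 * np.exp(-((centers - 2.2) ** 2) / 0.02) + 2.0 * np.exp(
            -((centers - 4.8) ** 2) / 0.02
        )
        curve = make_curve(g, bin_width=0.1)
        peaks = find_peaks(curve, min_height=1.0, min_separation=0.5)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(2.2, abs=0.1)
        assert peaks[1] == pytest.approx(4.8, abs=0.1)

    def test_flat_curve_no_peaks(self):
        assert find_peaks(make_curve(np.ones(50)), min_height=0.5) == []

    def test_monotone_curve_no_interior_peaks(self):
        assert find_peaks(make_curve(np.linspace(0, 5, 50)), min_height=0.5) == []

    def test_rescaling_invariance(self):
        g = np.concatenate([np.zeros(10), [5.0, 9.0, 5.0], np.zeros(10)])
        low = find_peaks(make_curve(g), min_height=1.0)
        high = find_peaks(make_curve(3 * g), min_height=1.0)
        assert low == high


class TestResidence:
    def event_trajectory(self, inside_frames, n_frames=40):
        # site at origin; ion near when "inside", 20 A away otherwise
        frames = np.zeros((n_frames, 2, 3))
        for f in range(n_frames):
            frames[f, 1, 0] = 2.0 if f in inside_frames else 20.0
        return Trajectory(
            frames=frames, groups={"protein": np.array([0]), "ions": np.array([1])}
        )

    def test_single_block(self):
        traj = self.event_trajectory(set(range(10, 30)))
        events = residence_events(traj, contact_cutoff=3.0, gap_tolerance=0)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (10, 29)
        assert events[0].duration_frames == 20

    def test_gap_merge(self):
        inside = set(range(10, 20)) | set(range(22, 31))
        traj = self.event_trajectory(inside)
        events = residence_events(traj, gap_tolerance=2)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (10, 30)
        # without tolerance the two runs stay separate
        assert len(residence_events(traj, gap_tolerance=1)) == 2

    def test_never_inside(self):
        assert residence_events(self.event_trajectory(set())) == []

    def test_merge_idempotent_and_bounded(self):
        rng = np.random.default_rng(8)
        inside = rng.random(200) < 0.3
        merged = merge_runs(inside, gap_tolerance=2)
        # merging the merged intervals again changes nothing
        flat = np.zeros(200, dtype=bool)
        for s, e in merged:
            flat[s : e + 1] = True
        assert merge_runs(flat, gap_tolerance=2) == merged
        assert sum(e - s + 1 for s, e in merged) <= 200

    def test_duration_ps_uses_frame_spacing(self):
        traj = self.event_trajectory(set(range(5)))
        traj.frame_spacing_ps = 10.0
        (event,) = residence_events(traj)
        assert event.duration_ps(traj.frame_spacing_ps) == pytest.approx(50.0)


class TestAssociationComparison:
    def test_identical_curves(self):
        curve = make_curve(np.linspace(1, 3, 30))
        assert compare_association(curve, curve, (0.5, 2.5)) == pytest.approx(1.0)

    def test_doubled_curve(self):
        a = make_curve(2 * np.ones(30))
        b = make_curve(np.ones(30))
        assert compare_association(a, b, (0.5, 2.5)) == pytest.approx(2.0)

    def test_enriched_mutant_fixture_exceeds_unity(self):
        protein = np.zeros((1, 3))
        wild = fx.make_ion_trajectory(
            protein, n_ions=30, n_frames=60, shells=[(2.7, 0.2)], uniform_weight=0.8, seed=14
        )
        mutant = fx.make_ion_trajectory(
            protein, n_ions=30, n_frames=60, shells=[(2.7, 0.6)], uniform_weight=0.4, seed=14
        )
        kwargs = dict(bin_width=0.25, r_max=8.0, seed=2)
        ratio = compare_association(
            rdf_min_distance(mutant, **kwargs), rdf_min_distance(wild, **kwargs), (2.0, 3.5)
        )
        assert ratio > 1.5

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError, match="binning"):
            compare_association(make_curve(np.ones(10)), make_curve(np.ones(20)), (0, 1))
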