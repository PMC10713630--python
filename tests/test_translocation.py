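"""Distance series, state segmentation, event detection, representatives."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ligandpath as lp
from ligandpath import synthetic as syn
from ligandpath.structure import Atom, Structure, Trajectory
from ligandpath.translocation import StateThresholds


def _series(values):
    return lp.DistanceSeries(np.asarray(values, float),
                             np.arange(len(values)), lp.SitePoint([0, 0, 0]))


class TestDistanceSeries:
    def test_ligand_fixed_at_site_gives_zero(self):
        atoms = [Atom(1, "CA", "C", "ALA", 1, "A", [10.0, 0, 0]),
                 Atom(2, "CA", "C", "ALA", 2, "A", [0, 10.0, 0]),
                 Atom(3, "C1", "C", "LIG", 1, "L", [1.0, 2.0, 3.0])]
        top = Structure(atoms)
        traj = Trajectory(top, np.repeat(top.coords[None], 4, axis=0))
        s = lp.distance_series(traj, "chain L", "chain A",
                               lp.SitePoint([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(s.distances, 0.0, atol=1e-12)

    def test_per_frame_alignment_invariance(self, receptor, site_coord):
        traj, _ = syn.make_translocation_trajectory(
            receptor, dwell_frames={"bulk": 4, "contact": 4, "entry": 4},
            seed=3)
        site = lp.SitePoint(site_coord)
        base = lp.distance_series(traj, "chain L", "chain A", site,
                                  align_each_frame=True)
        rng = np.random.default_rng(5)
        frames = traj.frames.copy()
        for f in range(1, traj.n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            frames[f] = frames[f] @ R.T + t
        moved = Trajectory(traj.topology, frames)
        got = lp.distance_series(moved, "chain L", "chain A", site,
                                 align_each_frame=True)
        np.testing.assert_allclose(got.distances, base.distances, atol=1e-6)

    def test_empty_selection_error(self, receptor):
        traj, _ = syn.make_translocation_trajectory(
            receptor, dwell_frames={"bulk": 3}, seed=1)
        with pytest.raises(ValueError, match="non-empty"):
            lp.distance_series(traj, "chain Z", "chain A",
                               lp.SitePoint([0, 0, 0]))


class TestSegmentation:
    def test_zero_noise_boundaries_exact(self):
        x = [40.0] * 30 + [25.0] * 30 + [15.0] * 30 + [8.0] * 30 + [2.0] * 30
        seg = lp.segment_states(_series(x), method="changepoint", n_states=5)
        assert seg.boundaries == [30, 60, 90, 120]
        assert seg.labels[0] == "bulk" and seg.labels[-1] == "binding"

    def test_monotone_ramp_threshold_states_in_order(self):
        x = np.linspace(40, 1, 120)
        seg = lp.segment_states(_series(x), method="threshold")
        order = list(dict.fromkeys(seg.labels))
        assert order == ["bulk", "contact", "entry", "vestibule", "binding"]

    def test_noisy_changepoint_recovery_within_3_frames(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.concatenate([
                rng.normal(mu, 0.5, 100)
                for mu in (25.0, 15.0, 8.0, 2.0)
            ])
            seg = lp.segment_states(_series(np.abs(x)), method="changepoint",
                                    n_states=4)
            assert len(seg.boundaries) == 3
            for got, true in zip(seg.boundaries, (100, 200, 300)):
                assert abs(got - true) <= 3

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lp.segment_states(_series([1.0] * 5), method="changepoint")

    def test_hysteresis_absorbs_short_runs(self):
        x = [20.0] * 20 + [8.0] * 1 + [20.0] * 20  # 1-frame spike
        seg = lp.segment_states(_series(x), method="threshold",
                                thresholds=StateThresholds(min_dwell=5))
        assert set(seg.labels) == {"contact"}


class TestEntryEvents:
    def test_never_approaches(self):
        ev = lp.detect_entry_events(_series([30.0] * 50))
        assert (ev.entered_vestibule, ev.fully_bound) == (False, False)

    def test_full_binding_with_first_frames(self):
        x = [30.0] * 10 + [8.0] * 6 + [2.0] * 6
        ev = lp.detect_entry_events(_series(x),
                                    StateThresholds(min_dwell=5))
        assert ev.entered_vestibule and ev.fully_bound
        assert ev.first_vestibule_frame == 10
        assert ev.first_binding_frame == 16

    def test_single_frame_spike_filtered(self):
        x = [30.0] * 20 + [8.0] + [30.0] * 20
        ev = lp.detect_entry_events(_series(x),
                                    StateThresholds(min_dwell=5))
        assert not ev.entered_vestibule

    def test_monotone_in_vestibule_threshold(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = np.abs(rng.uniform(1, 30, size=60))
            lo = lp.detect_entry_events(
                _series(x), StateThresholds(d_vestibule=7.0, min_dwell=3))
            hi = lp.detect_entry_events(
                _series(x), StateThresholds(d_vestibule=9.0, min_dwell=3))
            assert hi.entered_vestibule >= lo.entered_vestibule

    def test_segmentation_event_consistency(self, receptor):
        """A vestibule-labeled dwell of >= min_dwell implies an entry event."""
        thr = StateThresholds()
        for seed in range(5):
            traj, _ = syn.make_translocation_trajectory(
                receptor, dwell_frames={"bulk": 20, "contact": 20,
                                        "entry": 20, "vestibule": 20},
                noise_sd=0.4, seed=seed)
            series = lp.distance_series(
                traj, "chain L", "chain A",
                lp.SitePoint(receptor.metadata["cavity_center"]))
            seg = lp.segment_states(series, method="threshold", thresholds=thr)
            ev = lp.detect_entry_events(series, thr)
            runs = [b - a for a, b, lab in seg.segments() if lab == "vestibule"]
            if any(r >= thr.min_dwell for r in runs):
                assert ev.entered_vestibule


class TestSummarize:
    def test_empty(self):
        assert lp.summarize_cohort([]) == (0, 0, 0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        events = []
        for _ in range(50):
            v = bool(rng.integers(2))
            b = bool(rng.integers(2)) and v
            events.append(lp.EntryEvents(v, b))
        n, nv, nb = lp.summarize_cohort(events)
        assert n == 50
        assert nv == sum(e.entered_vestibule for e in events)
        assert nb == sum(e.fully_bound for e in events)


class TestRepresentativeFrames:
    def _blob_trajectory(self, blobs, seed=0):
        """Single-atom 'ligand' whose position jumps between blobs."""
        rng = np.random.default_rng(seed)
        coords = np.vstack([
            center + rng.normal(0, 0.2, size=(n, 3))
            for center, n in blobs
        ])
        top = Structure([Atom(1, "C1", "C", "LIG", 1, "L", [0, 0, 0])])
        return Trajectory(top, coords[:, None, :])

    def test_identical_frames_degenerate(self):
        top = Structure([Atom(1, "C1", "C", "LIG", 1, "L", [1, 1, 1])])
        traj = Trajectory(top, np.ones((12, 1, 3)))
        seg = lp.StateSegmentation(labels=["binding"] * 12, boundaries=[],
                                   method="threshold")
        reps = lp.select_representative_frames(traj, seg, "chain L", k=4)
        assert reps["binding"] in range(12)

    def test_majority_blob_wins(self):
        traj = self._blob_trajectory([(np.array([0, 0, 0]), 30),
                                      (np.array([20, 0, 0]), 10)], seed=1)
        seg = lp.StateSegmentation(labels=["entry"] * 40, boundaries=[],
                                   method="threshold")
        reps = lp.select_representative_frames(traj, seg, "chain L", k=2)
        assert reps["entry"] < 30  # from the 30-frame blob

    def test_medoid_matches_brute_force(self):
        centers = [np.array(c) for c in
                   ([0, 0, 0], [15, 0, 0], [0, 15, 0], [0, 0, 15])]
        traj = self._blob_trajectory([(c, 10 + 5 * i)
                                      for i, c in enumerate(centers)], seed=2)
        n = traj.n_frames
        seg = lp.StateSegmentation(labels=["vestibule"] * n, boundaries=[],
                                   method="threshold")
        reps = lp.select_representative_frames(traj, seg, "chain L", k=4,
                                               seed=0)
        # largest blob is the last one (25 frames); brute-force medoid
        X = traj.frames[:, 0, :]
        members = np.arange(n - 25, n)
        centroid = X[members].mean(axis=0)
        best = members[np.argmin(np.linalg.norm(X[members] - centroid, axis=1))]
        assert reps["vestibule"] == best

    def test_determinism(self, receptor):
        traj, _ = syn.make_translocation_trajectory(
            receptor, dwell_frames={"bulk": 15, "contact": 15}, noise_sd=0.5,
            seed=4)
        series = lp.distance_series(
            traj, "chain L", "chain A",
            lp.SitePoint(receptor.metadata["cavity_center"]))
        seg = lp.segment_states(series, method="threshold")
        a = lp.select_representative_frames(traj, seg, "chain L", seed=11)
        b = lp.select_representative_frames(traj, seg, "chain L", seed=11)
        assert a == b
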