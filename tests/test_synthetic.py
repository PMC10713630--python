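"""The generators themselves: determinism, planted geometry, feasibility."""

import numpy as np
import pytest

import ligandpath as lp
from ligandpath import synthetic as syn
from ligandpath.synthetic import ColumnIdentityPlan


class TestToyReceptor:
    def test_cavity_is_empty(self, receptor, site_coord):
        d = np.linalg.norm(receptor.coords - site_coord, axis=1)
        assert d.min() > 5.0

    def test_determinism(self):
        a = syn.make_toy_receptor(400, cavity_radius=2.0, seed=42)
        b = syn.make_toy_receptor(400, cavity_radius=2.0, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_cavity_larger_than_shell_rejected(self):
        with pytest.raises(ValueError, match="too few residues"):
            syn.make_toy_receptor(300, cavity_radius=8.0, seed=0)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            syn.make_toy_receptor(500, cavity_radius=-1.0)


class TestTranslocationTrajectory:
    def test_zero_noise_plateaus_exact(self, receptor, site_coord):
        planted = {"bulk": 40.0, "contact": 25.0, "entry": 15.0,
                   "vestibule": 8.0, "binding": 2.0}
        traj, truth = syn.make_translocation_trajectory(
            receptor, planted_distances=planted,
            dwell_frames={s: 10 for s in planted}, noise_sd=0.0, seed=1)
        series = lp.distance_series(traj, "chain L", "chain A",
                                    lp.SitePoint(site_coord))
        for f, state in enumerate(truth.state_schedule):
            assert series.distances[f] == pytest.approx(planted[state], abs=1e-9)

    def test_truncated_schedule_not_fully_bound(self, receptor):
        traj, truth = syn.make_translocation_trajectory(
            receptor, dwell_frames={"bulk": 5, "contact": 5, "entry": 5,
                                    "vestibule": 5}, seed=2)
        assert truth.entered_vestibule is True
        assert truth.fully_bound is False

    def test_inconsistent_state_order_rejected(self, receptor):
        with pytest.raises(ValueError, match="order"):
            syn.make_translocation_trajectory(
                receptor, dwell_frames={"contact": 5, "bulk": 5})

    def test_determinism(self, receptor):
        kwargs = dict(dwell_frames={"bulk": 5, "contact": 5}, n_waters=30,
                      noise_sd=0.3, seed=12)
        t1, _ = syn.make_translocation_trajectory(receptor, **kwargs)
        t2, _ = syn.make_translocation_trajectory(receptor, **kwargs)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_contact_truth_from_emitted_coordinates(self, receptor):
        """Truth contact frames agree with an in-test independent re-scan."""
        traj, truth = syn.make_translocation_trajectory(
            receptor, dwell_frames={"bulk": 3, "contact": 3, "entry": 3,
                                    "vestibule": 3, "binding": 3}, seed=6)
        top = traj.topology
        lig_idx = top.select("chain L")
        rec_idx = top.select("chain A")
        rescan: dict = {}
        for f in range(traj.n_frames):
            lig = traj.frames[f][lig_idx]
            for i in rec_idx:
                d = np.linalg.norm(lig - traj.frames[f][i], axis=1).min()
                if d <= 4.0:
                    rescan.setdefault(top.atoms[i].residue_key, set()).add(f)
        assert {k: frozenset(v) for k, v in rescan.items()} == truth.contact_schedule


class TestCohort:
    @pytest.mark.parametrize("counts", [(4, 0, 0), (6, 6, 6), (8, 3, 1)])
    def test_planted_counts(self, receptor, counts):
        n, e, b = counts
        trajs, truth = syn.make_cohort(receptor, n, e, b, seed=5)
        assert len(trajs) == n
        assert (truth.n_trajectories, truth.n_vestibule_entries,
                truth.n_full_bindings) == counts

    def test_ordering_violation_rejected(self, receptor):
        with pytest.raises(ValueError):
            syn.make_cohort(receptor, 5, 2, 3)

    def test_truth_invariant(self, receptor):
        _, truth = syn.make_cohort(receptor, 7, 4, 2, seed=8)
        assert (truth.n_full_bindings <= truth.n_vestibule_entries
                <= truth.n_trajectories)


class TestBulkWater:
    def test_zero_density_means_no_shell_waters(self):
        lig = syn.make_toy_receptor(400, cavity_radius=2.0, seed=0)
        lig = lig.subset(range(5))
        box = syn.make_bulk_water_system(lig, density=1e-9, seed=1, n_frames=3)
        for f in range(box.n_frames):
            with pytest.warns(UserWarning):
                assert lp.shell_count(box.topology, box.frames[f], "chain L") == 0

    def test_doubling_density_doubles_shell_count(self):
        rng = np.random.default_rng(3)
        from ligandpath.structure import Atom, Structure
        lig = Structure([Atom(i + 1, f"C{i}", "C", "LIG", 1, "L", c)
                         for i, c in enumerate(rng.normal(size=(8, 3)))])
        means = []
        for dens in (0.0334, 0.0668):
            box = syn.make_bulk_water_system(lig, density=dens, seed=7,
                                             n_frames=20)
            means.append(lp.bulk_reference(box, "chain L"))
        assert means[1] == pytest.approx(2.0 * means[0], rel=0.25)

    def test_box_too_small_rejected(self):
        from ligandpath.structure import Atom, Structure
        lig = Structure([Atom(1, "C1", "C", "LIG", 1, "L", [0, 0, 0]),
                         Atom(2, "C2", "C", "LIG", 1, "L", [15, 0, 0])])
        with pytest.raises(ValueError, match="too small"):
            syn.make_bulk_water_system(lig, box_edge=20.0)


class TestAlignmentGenerator:
    def test_planted_identity_and_similarity(self):
        aln = syn.make_alignment(
            6, 120, ColumnIdentityPlan(list(range(100)), 0.73, 0.82), seed=1)
        pc = lp.pocket_identity(aln, "seq0001", "seq0002", list(range(100)))
        assert (pc.identity_pct, pc.similarity_pct) == (73.0, 82.0)

    def test_identical_plan(self):
        aln = syn.make_alignment(
            3, 30, ColumnIdentityPlan(list(range(20)), 1.0, 1.0), seed=2)
        pc = lp.pocket_identity(aln, "seq0001", "seq0002", list(range(20)))
        assert (pc.identity_pct, pc.similarity_pct) == (100.0, 100.0)

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="not a multiple"):
            syn.make_alignment(
                4, 30, ColumnIdentityPlan(list(range(16)), 0.47), seed=0)


class TestComplementarityCases:
    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown case kind"):
            syn.make_complementarity_case("bogus")

    def test_match_scores_above_clash(self):
        lm, em = syn.make_complementarity_case("hydrophobic_match")
        lc, ec = syn.make_complementarity_case("hydrophobic_clash")
        assert lp.hydrophobic_match(lm, em) > lp.hydrophobic_match(lc, ec)
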