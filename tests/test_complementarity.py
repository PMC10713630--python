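"""Surface sampling, MHP fields, and complementarity sign/ordering behavior."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ligandpath as lp
from ligandpath import synthetic as syn
from ligandpath.complementarity import flip_pose, mhp_field, sample_surface
from ligandpath.structure import Atom, Structure


def _ligand(coords, elements=None, charges=None):
    elements = elements or ["C"] * len(coords)
    charges = charges or [None] * len(coords)
    return Structure([
        Atom(i + 1, f"{e}{i + 1}", e, "LIG", 1, "L", c, charge=q)
        for i, (c, e, q) in enumerate(zip(coords, elements, charges))
    ])


class TestSampleSurface:
    def test_single_atom_analytic_sphere(self):
        lig = _ligand([[0.0, 0, 0]])
        surf = sample_surface(lig, probe=1.4, density=1.0)
        r = np.linalg.norm(surf.points, axis=1)
        np.testing.assert_allclose(r, 3.1, atol=1e-9)
        assert surf.areas.sum() == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.05)

    def test_fully_overlapping_atoms_same_surface_as_one(self):
        one = sample_surface(_ligand([[0.0, 0, 0]]))
        two = sample_surface(_ligand([[0.0, 0, 0], [0.0, 0, 0]]))
        # coincident spheres: every point of each lattice survives
        assert two.n_points == 2 * one.n_points

    def test_dumbbell_count_matches_rejection_sampling(self):
        lig = _ligand([[0.0, 0, 0], [2.5, 0, 0]])
        surf = sample_surface(lig, density=4.0)
        exposed_frac = {}
        rng = np.random.default_rng(0)
        for i, center in enumerate([[0.0, 0, 0], [2.5, 0, 0]]):
            d = rng.normal(size=(20000, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            pts = np.asarray(center) + 3.1 * d
            other = np.array([2.5, 0, 0]) if i == 0 else np.zeros(3)
            exposed_frac[i] = (np.linalg.norm(pts - other, axis=1) >= 3.1).mean()
        expected = sum(exposed_frac.values()) * np.ceil(4 * np.pi * 3.1 ** 2 * 4)
        assert surf.n_points == pytest.approx(expected, rel=0.05)

    def test_no_heavy_atoms_error(self):
        s = Structure([Atom(1, "H1", "H", "LIG", 1, "L", [0.0, 0, 0])])
        with pytest.raises(ValueError):
            sample_surface(s)


class TestMhpField:
    def test_single_term(self):
        pts = np.array([[2.0, 0, 0]])
        val = mhp_field(pts, np.zeros((1, 3)), [1.0], decay_length=2.0)
        assert val[0] == pytest.approx(np.exp(-1.0))

    def test_zero_constants(self):
        rng = np.random.default_rng(1)
        val = mhp_field(rng.normal(size=(20, 3)), rng.normal(size=(5, 3)),
                        np.zeros(5))
        np.testing.assert_array_equal(val, 0.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 3))
        atoms = rng.normal(size=(10, 3))
        consts = rng.normal(size=10)
        got = mhp_field(pts, atoms, consts, decay_length=1.7)
        expected = np.array([
            sum(c * np.exp(-np.linalg.norm(p - a) / 1.7)
                for a, c in zip(atoms, consts))
            for p in pts
        ])
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestHydrophobicMatch:
    def test_match_positive_clash_negative(self):
        lm, em = syn.make_complementarity_case("hydrophobic_match")
        lc, ec = syn.make_complementarity_case("hydrophobic_clash")
        assert lp.hydrophobic_match(lm, em) > 0
        assert lp.hydrophobic_match(lc, ec) < 0

    def test_rigid_motion_invariance(self):
        from ligandpath.complementarity import SurfacePointSet

        lm, em = syn.make_complementarity_case("hydrophobic_match")
        surf = sample_surface(lm)
        base = lp.hydrophobic_match(lm, em, surface=surf)
        R = Rotation.from_euler("xyz", [0.5, 1.1, -0.7]).as_matrix()
        t = np.array([3.0, -8.0, 2.0])
        lm2 = lm.with_coords(lm.coords @ R.T + t)
        em2 = em.with_coords(em.coords @ R.T + t)
        # exact when the surface is transported with the complex
        moved_surf = SurfacePointSet(surf.points @ R.T + t, surf.areas,
                                     surf.owner_atom)
        assert lp.hydrophobic_match(lm2, em2, surface=moved_surf) == \
               pytest.approx(base, abs=1e-6)
        # re-sampling the lattice in the rotated frame only adds tiny
        # quadrature noise
        assert lp.hydrophobic_match(lm2, em2) == pytest.approx(base, abs=1e-3)

    def test_zero_variance_error(self):
        lig = _ligand([[0.0, 0, 0]])
        env = _ligand([[0.0, 0, 0]])  # equidistant single atom: flat fields
        with pytest.raises(ValueError, match="zero-variance"):
            lp.hydrophobic_match(lig, env)


class TestElectrostaticComplementarity:
    def test_perfect_case_above_0_9(self):
        lig, env = syn.make_complementarity_case("perfect_electrostatic")
        assert lp.electrostatic_complementarity(lig, env) >= 0.9

    def test_anti_case_below_minus_0_9(self):
        lig, env = syn.make_complementarity_case("anti_electrostatic")
        assert lp.electrostatic_complementarity(lig, env) <= -0.9

    def test_charge_flip_negates_exactly(self):
        lig, env = syn.make_complementarity_case("perfect_electrostatic")
        flipped = Structure([
            Atom(a.serial, a.name, a.element, a.res_name, a.res_id, a.chain,
                 a.coord, charge=-a.charge, radius=a.radius)
            for a in env.atoms
        ])
        s1 = lp.electrostatic_complementarity(lig, env)
        s2 = lp.electrostatic_complementarity(lig, flipped)
        assert s2 == pytest.approx(-s1, abs=1e-12)

    def test_uncorrelated_charges_near_zero(self):
        # null: two parallel 40-atom chains with tight surfaces, so the
        # fields carry many independent spatial modes; i.i.d. charges give
        # near-zero complementarity in either direction
        n = 40
        lig_coords = np.stack([1.5 * np.arange(n), np.zeros(n), np.zeros(n)],
                              axis=1)
        env_coords = lig_coords + np.array([0.75, 2.6, 0.0])

        def chain(coords, charges):
            return Structure([
                Atom(i + 1, f"C{i + 1}", "C", "LIG", 1, "L", c, charge=q,
                     radius=0.8)
                for i, (c, q) in enumerate(zip(coords, charges))
            ])

        for seed in range(10):
            r = np.random.default_rng(seed)
            lig = chain(lig_coords.tolist(), r.normal(size=n).tolist())
            env = chain(env_coords.tolist(), r.normal(size=n).tolist())
            score = lp.electrostatic_complementarity(lig, env, probe=0.4)
            assert abs(score) < 0.5

    def test_missing_charges_error(self):
        lig = _ligand([[0.0, 0, 0], [2.0, 0, 0]])
        env = _ligand([[5.0, 0, 0]])
        with pytest.raises(ValueError, match="no charge"):
            lp.electrostatic_complementarity(lig, env)


class TestRankPoses:
    def test_identical_poses_identical_scores(self):
        lig, env = syn.make_complementarity_case("hydrophobic_match")
        table = lp.rank_poses([("a", lig), ("b", lig)], env)
        assert table.loc[0, "hydrophobic_match"] == \
               table.loc[1, "hydrophobic_match"]

    def test_planted_pose_beats_flip_on_both_metrics(self):
        lig, env = syn.make_complementarity_case("hydrophobic_match")
        table = lp.rank_poses(
            [("pose", lig), ("reverted", flip_pose(lig, (0, 0, 1)))],
            env).set_index("pose")
        assert table.loc["pose", "hydrophobic_match"] > \
               table.loc["reverted", "hydrophobic_match"]
        assert table.loc["pose", "electrostatic_complementarity"] > \
               table.loc["reverted", "electrostatic_complementarity"]

    def test_ordering_matches_individual_scores(self):
        lig, env = syn.make_complementarity_case("hydrophobic_match")
        poses = [("pose", lig), ("flipped", flip_pose(lig, (0, 0, 1)))]
        table = lp.rank_poses(poses, env, sort_by="hydrophobic_match")
        individual = sorted(
            ((name, lp.hydrophobic_match(p, env)) for name, p in poses),
            key=lambda x: -x[1])
        assert list(table["pose"]) == [name for name, _ in individual]
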