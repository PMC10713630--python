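"""Geometric primitives against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import ligandpath as lp
from ligandpath.structure import Atom, Structure


def _atoms(coords, element="C"):
    return Structure([
        Atom(i + 1, f"X{i}", element, "ALA", i + 1, "A", c)
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ])


class TestCenterOfMass:
    def test_two_equal_atoms(self):
        s = _atoms([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(lp.center_of_mass(s), [1, 0, 0])

    def test_single_atom(self):
        s = _atoms([[3.0, -1.0, 2.5]])
        np.testing.assert_allclose(lp.center_of_mass(s), [3.0, -1.0, 2.5])

    def test_mass_weighting_matches_direct_sum(self):
        rng = np.random.default_rng(4)
        elements = rng.choice(["C", "N", "O", "S", "H"], size=50)
        coords = rng.normal(size=(50, 3))
        s = Structure([
            Atom(i + 1, f"X{i}", e, "ALA", i + 1, "A", c)
            for i, (e, c) in enumerate(zip(elements, coords))
        ])
        m = s.masses()
        expected = (m[:, None] * coords).sum(axis=0) / m.sum()
        np.testing.assert_allclose(lp.center_of_mass(s), expected, atol=1e-12)

    def test_geometric_weighting(self):
        s = _atoms([[0, 0, 0], [1, 0, 0]], element="C")
        s.atoms[0].element = "S"  # heavier: mass COM shifts toward it
        mass_com = lp.center_of_mass(s, weighting="mass")
        geo_com = lp.center_of_mass(s, weighting="geometric")
        np.testing.assert_allclose(geo_com, [0.5, 0, 0])
        assert mass_com[0] < 0.5

    def test_empty_selection_error(self):
        s = _atoms([[0, 0, 0]])
        with pytest.raises(ValueError, match="empty"):
            lp.center_of_mass(s, "chain Z")


class TestKabsch:
    def test_recovers_90_degree_rotation(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R.T
        res = lp.kabsch_superpose(P, Q)
        assert res.rmsd < 1e-8
        np.testing.assert_allclose(res.rotation, R, atol=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(8, 3))
        res = lp.kabsch_superpose(P, P)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0, atol=1e-10)

    def test_rmsd_matches_direct_postfit_computation(self):
        rng = np.random.default_rng(2)
        P = rng.normal(scale=5, size=(20, 3))
        R = Rotation.random(rng=3).as_matrix()
        Q = P @ R.T + rng.normal(scale=0.1, size=(20, 3)) + [4, 5, 6]
        res = lp.kabsch_superpose(P, Q)
        direct = np.sqrt(((res.apply(P) - Q) ** 2).sum(axis=1).mean())
        assert res.rmsd == pytest.approx(direct, abs=1e-12)
        assert 0.05 <= res.rmsd <= 0.2

    def test_reflection_branch_corrected(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(12, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image: best proper rotation is not a reflection
        res = lp.kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(15, 3))
        Q = rng.normal(size=(15, 3))
        res = lp.kabsch_superpose(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lp.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            lp.kabsch_superpose(line, line)

    def test_superposed_rmsd_never_above_unsuperposed(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))
            res = lp.kabsch_superpose(P, Q)
            raw = np.sqrt(((P - Q) ** 2).sum(axis=1).mean())
            assert res.rmsd <= raw + 1e-12


class TestNeighborPairs:
    def test_boundary_inclusive(self):
        a = np.array([[0.0, 0, 0]])
        assert len(lp.neighbor_pairs(a, np.array([[3.99, 0, 0]]), 4.0)) == 1
        assert len(lp.neighbor_pairs(a, np.array([[4.01, 0, 0]]), 4.0)) == 0
        assert len(lp.neighbor_pairs(a, np.array([[4.00, 0, 0]]), 4.0)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_set_equal_to_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 30, size=(200, 3))
        B = rng.uniform(0, 30, size=(200, 3))
        got = {(i, j) for i, j, _ in lp.neighbor_pairs(A, B, 3.0)}
        expected = set(zip(*np.nonzero(cdist(A, B) <= 3.0)))
        assert got == expected

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 10, size=(50, 3))
        B = rng.uniform(0, 10, size=(50, 3))
        ab = {(i, j) for i, j, _ in lp.neighbor_pairs(A, B, 3.0)}
        ba = {(j, i) for i, j, _ in lp.neighbor_pairs(B, A, 3.0)}
        assert ab == ba
        R = Rotation.random(rng=9).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = {(i, j) for i, j, _ in
                 lp.neighbor_pairs(A @ R.T + t, B @ R.T + t, 3.0)}
        assert ab == moved


class TestMapReferenceSite:
    def _pairing(self, n):
        return [(("A", i), ("A", i)) for i in range(1, n + 1)]

    def test_identity_mapping(self, receptor):
        sp = lp.map_reference_site(receptor, "resid 1:10", receptor,
                                   self._pairing(20))
        expected = lp.center_of_mass(receptor, "resid 1:10")
        np.testing.assert_allclose(sp.coord, expected, atol=1e-8)

    def test_rigid_shift_covariance(self, receptor):
        shift = np.array([10.0, 0.0, 0.0])
        target = receptor.with_coords(receptor.coords + shift)
        sp = lp.map_reference_site(receptor, "resid 1:10", target,
                                   self._pairing(20))
        expected = lp.center_of_mass(receptor, "resid 1:10") + shift
        np.testing.assert_allclose(sp.coord, expected, atol=1e-8)

    def test_rotation_covariance(self, receptor):
        R = Rotation.from_euler("xyz", [0.4, -0.2, 1.0]).as_matrix()
        target = receptor.with_coords(receptor.coords @ R.T)
        sp = lp.map_reference_site(receptor, "resid 1:10", target,
                                   self._pairing(20))
        expected = R @ lp.center_of_mass(receptor, "resid 1:10")
        np.testing.assert_allclose(sp.coord, expected, atol=1e-6)

    def test_planted_cavity_site(self, receptor, site_coord):
        """A reference ligand placed at the cavity center maps back onto it."""
        from ligandpath.structure import Atom, Structure

        lig = [Atom(receptor.n_atoms + 1, "C1", "C", "LIG", 1, "L",
                    site_coord)]
        ref = Structure(list(receptor.atoms) + lig,
                        metadata=receptor.metadata)
        sp = lp.map_reference_site(ref, "chain L", receptor, self._pairing(10))
        np.testing.assert_allclose(sp.coord, site_coord, atol=1e-8)

    def test_unpaired_residue_error(self, receptor):
        with pytest.raises(ValueError, match="unpaired"):
            lp.map_reference_site(receptor, "resid 1:10", receptor,
                                  [(("A", 1), ("A", 99999)),
                                   (("A", 2), ("A", 2)),
                                   (("A", 3), ("A", 3))])
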