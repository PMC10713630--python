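"""Geometric primitives: centers of mass, Kabsch superposition, reference-site
mapping, and cutoff neighbor search.

No periodic-boundary handling anywhere: trajectories are assumed imaged and
whole, which holds for a solvated receptor whose ligand path never wraps.
All cutoff comparisons are inclusive (``distance <= cutoff``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "SitePoint",
    "SuperpositionResult",
    "center_of_mass",
    "kabsch_superpose",
    "map_reference_site",
    "neighbor_pairs",
]


@dataclass
class SitePoint:
    """A reference point (e.g. a mapped binding-site center) in the target frame."""

    coord: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("SitePoint coord must be a finite 3-vector")


@dataclass
class SuperpositionResult:
    """A proper rotation + translation minimizing weighted RMSD."""

    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # 3-vector
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform: x -> R x + t."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def center_of_mass(
    structure: Structure,
    selection="all",
    weighting: str = "mass",
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Center of mass (or geometric center) of a selection.

    ``frame`` optionally supplies alternative coordinates (a trajectory
    frame) for the same topology.
    """
    idx = structure.select(selection)
    if idx.size == 0:
        raise ValueError("empty selection in center_of_mass")
    coords = structure.coords if frame is None else np.asarray(frame, dtype=float)
    pts = coords[idx]
    if weighting == "geometric":
        return pts.mean(axis=0)
    if weighting == "mass":
        w = structure.masses(idx)
        return (w[:, None] * pts).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal proper-rotation superposition of paired coordinate sets.

    Returns the transform that carries ``mobile`` onto ``reference`` with
    minimum weighted RMSD; the reflection branch of the SVD solution is
    corrected so the rotation determinant is +1.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(reference_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cm_p = w @ P
    cm_q = w @ Q
    Pc = P - cm_p
    Qc = Q - cm_q
    if np.linalg.matrix_rank(Pc * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise ValueError("superposition points are collinear or degenerate")
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cm_q - R @ cm_p
    fitted = P @ R.T + t
    rmsd = float(np.sqrt((w * ((fitted - Q) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _ca_coords_for_pairing(
    structure: Structure,
    residues: Sequence[tuple[str, int]],
    frame: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    coords = structure.coords if frame is None else np.asarray(frame, dtype=float)
    out = []
    missing = []
    for key in residues:
        key = (key[0], int(key[1]))
        atom_idx = structure.residue_index.get(key)
        ca = None
        if atom_idx is not None:
            for i in atom_idx:
                if structure.atoms[i].name == "CA":
                    ca = i
                    break
            if ca is None:  # single-atom pseudo-residues count as their own anchor
                ca = atom_idx[0]
        if ca is None:
            missing.append(key)
        else:
            out.append(coords[ca])
    if missing:
        raise ValueError(f"unpaired anchor residues: {missing}")
    return np.asarray(out), missing


def map_reference_site(
    reference_complex: Structure,
    reference_ligand_selection,
    target: Structure,
    pairing: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    target_frame: np.ndarray | None = None,
    weighting: str = "mass",
) -> SitePoint:
    """Map a reference-ligand center of mass into a target structure's frame.

    The C-alpha anchors of the reference residues in ``pairing`` are
    superposed onto the paired target anchors (Kabsch); the resulting rigid
    transform is applied to the reference ligand's center of mass.  This is
    how a buried-site center defined by a ligand in a reference complex
    (e.g. eugenol in an odorant-receptor structure) is expressed in the
    frame of a homolog model.
    """
    if len(pairing) < 3:
        raise ValueError("pairing must supply at least 3 residue pairs")
    ref_keys = [p[0] for p in pairing]
    tgt_keys = [p[1] for p in pairing]
    ref_anchor, _ = _ca_coords_for_pairing(reference_complex, ref_keys)
    tgt_anchor, _ = _ca_coords_for_pairing(target, tgt_keys, frame=target_frame)
    sup = kabsch_superpose(ref_anchor, tgt_anchor)
    com = center_of_mass(reference_complex, reference_ligand_selection, weighting)
    return SitePoint(coord=sup.apply(com[None, :])[0],
                     source=f"reference ligand COM mapped via {sup.n_pairs} anchors")


def neighbor_pairs(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
) -> list[tuple[int, int, float]]:
    """All index pairs (i in A, j in B) with Euclidean distance <= cutoff.

    Backed by a k-d tree; output order is (i, j) lexicographic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    B = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if A.size == 0 or B.size == 0:
        return []
    tree_b = cKDTree(B)
    hits = cKDTree(A).query_ball_tree(tree_b, r=cutoff)
    pairs: list[tuple[int, int, float]] = []
    for i, js in enumerate(hits):
        for j in sorted(js):
            d = float(np.linalg.norm(A[i] - B[j]))
            if d <= cutoff:  # guard against tree padding at the boundary
                pairs.append((i, j, d))
    return pairs
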