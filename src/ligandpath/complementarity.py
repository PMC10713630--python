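"""Surface-based hydrophobic and electrostatic complementarity scores.

Both scores are evaluated on the ligand's solvent-accessible surface
(Fibonacci point lattices on probe-expanded atom spheres):

* hydrophobic match — the Pearson correlation between the ligand-sourced
  and environment-sourced molecular hydrophobicity potential (MHP), a
  distance-decayed sum of atomic hydrophobicity constants; positive means
  hydrophobic ligand patches face a hydrophobic environment;
* electrostatic complementarity — minus the Pearson correlation between the
  ligand- and environment-generated Coulomb potentials (dielectric folds
  out of a correlation); +1 is perfect charge complementarity.

These are first-principles correlates of the proprietary tools used for
such scoring, defined for sign and ordering behavior (pose ranking, flipped
poses), not for absolute-score comparability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "SurfacePointSet",
    "ComplementarityScore",
    "atomic_hydrophobicity",
    "sample_surface",
    "mhp_field",
    "hydrophobic_match",
    "electrostatic_complementarity",
    "flip_pose",
    "rank_poses",
]

#: Atomic hydrophobicity constants by element: aromatic C > aliphatic C > S
#: > halogens > N > O, with charged N/O the most hydrophilic.
ELEMENT_HYDROPHOBICITY = {
    "C": 0.5, "S": 0.3, "F": 0.2, "CL": 0.25, "BR": 0.25, "I": 0.25,
    "P": -0.2, "N": -0.4, "O": -0.6, "H": 0.0,
}
AROMATIC_CARBON = 0.7
CHARGED_POLAR = -1.0
_CHARGE_THRESHOLD = 0.3


def atomic_hydrophobicity(atom) -> float:
    """Bundled per-atom hydrophobicity constant.

    Charged (|q| >= 0.3 e) nitrogens/oxygens are the most hydrophilic;
    carbons in atoms flagged aromatic (name containing 'AR') score as
    aromatic.  Override per atom via the ``*_constants`` arguments of the
    scoring functions when finer typing is needed.
    """
    el = atom.element.upper()
    if el in {"N", "O"} and atom.charge is not None \
            and abs(atom.charge) >= _CHARGE_THRESHOLD:
        return CHARGED_POLAR
    if el == "C" and "AR" in atom.name.upper():
        return AROMATIC_CARBON
    try:
        return ELEMENT_HYDROPHOBICITY[el]
    except KeyError:
        raise KeyError(f"no hydrophobicity constant for element {el!r} "
                       f"(atom {atom.serial})")


@dataclass
class SurfacePointSet:
    """Points on the probe-expanded ligand surface with per-point areas."""

    points: np.ndarray
    areas: np.ndarray
    owner_atom: np.ndarray

    def __post_init__(self) -> None:
        if self.points.shape[0] < 1:
            raise ValueError("surface sampling produced no points")
        if np.any(self.areas <= 0):
            raise ValueError("surface point areas must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class ComplementarityScore:
    """Pose-level complementarity (both metrics in [-1, 1])."""

    hydrophobic_match: float
    electrostatic_complementarity: float
    n_points: int


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, 1.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def sample_surface(
    ligand: Structure,
    probe: float = 1.4,
    density: float = 1.0,
) -> SurfacePointSet:
    """Quasi-uniform points on the ligand's solvent-accessible surface.

    Each heavy atom's sphere of radius ``vdW + probe`` gets a Fibonacci
    lattice at ``density`` points/A^2; points buried inside another
    expanded sphere are removed.  Fully deterministic.
    """
    heavy = ligand.select("heavy")
    if heavy.size == 0:
        raise ValueError("ligand has no heavy atoms")
    coords = ligand.coords[heavy]
    radii = ligand.radii(heavy) + probe
    points, areas, owners = [], [], []
    for i in range(len(heavy)):
        r = radii[i]
        n = max(8, int(np.ceil(density * 4.0 * np.pi * r ** 2)))
        sphere = coords[i] + r * _fibonacci_sphere(n)
        d = cdist(sphere, coords)
        others = np.ones(len(heavy), dtype=bool)
        others[i] = False
        exposed = np.all(d[:, others] >= radii[others][None, :] - 1e-9, axis=1) \
            if others.any() else np.ones(n, dtype=bool)
        kept = sphere[exposed]
        points.append(kept)
        areas.append(np.full(kept.shape[0], 4.0 * np.pi * r ** 2 / n))
        owners.append(np.full(kept.shape[0], heavy[i], dtype=int))
    return SurfacePointSet(
        points=np.vstack(points),
        areas=np.concatenate(areas),
        owner_atom=np.concatenate(owners),
    )


def mhp_field(
    points: np.ndarray,
    atom_coords: np.ndarray,
    constants: np.ndarray,
    decay_length: float = 2.0,
) -> np.ndarray:
    """MHP(p) = sum_i f_i * exp(-d(p, atom_i) / decay_length)."""
    constants = np.asarray(constants, dtype=float)
    d = cdist(np.asarray(points, float), np.asarray(atom_coords, float))
    return np.exp(-d / decay_length) @ constants


def _constants_for(structure: Structure, idx: np.ndarray,
                   override: Sequence[float] | None) -> np.ndarray:
    if override is not None:
        arr = np.asarray(override, dtype=float)
        if arr.shape != (idx.size,):
            raise ValueError("constants override length must match heavy-atom count")
        return arr
    return np.array([atomic_hydrophobicity(structure.atoms[i]) for i in idx])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise ValueError("zero-variance field: complementarity undefined")
    return float(np.corrcoef(x, y)[0, 1])


def hydrophobic_match(
    ligand: Structure,
    environment: Structure,
    probe: float = 1.4,
    decay_length: float = 2.0,
    density: float = 1.0,
    ligand_constants: Sequence[float] | None = None,
    env_constants: Sequence[float] | None = None,
    surface: SurfacePointSet | None = None,
) -> float:
    """Correlation of ligand- vs environment-sourced MHP on the ligand surface."""
    lig_idx = ligand.select("heavy")
    env_idx = environment.select("heavy")
    if lig_idx.size == 0 or env_idx.size == 0:
        raise ValueError("ligand and environment must have heavy atoms")
    surf = surface or sample_surface(ligand, probe, density)
    f_lig = mhp_field(surf.points, ligand.coords[lig_idx],
                      _constants_for(ligand, lig_idx, ligand_constants),
                      decay_length)
    f_env = mhp_field(surf.points, environment.coords[env_idx],
                      _constants_for(environment, env_idx, env_constants),
                      decay_length)
    return _pearson(f_lig, f_env)


def _coulomb_potential(points: np.ndarray, coords: np.ndarray,
                       charges: np.ndarray) -> np.ndarray:
    d = cdist(points, coords)
    d = np.maximum(d, 1e-6)
    return (1.0 / d) @ charges


def electrostatic_complementarity(
    ligand: Structure,
    environment: Structure,
    probe: float = 1.4,
    density: float = 1.0,
    surface: SurfacePointSet | None = None,
) -> float:
    """Minus the correlation of ligand vs environment Coulomb potentials.

    +1 means the environment's potential mirrors the ligand's with opposite
    sign everywhere on the ligand surface (perfect complementarity).
    Requires partial charges on both sides (e.g. from PQR input).
    """
    lig_idx = ligand.select("heavy")
    env_idx = environment.select("heavy")
    surf = surface or sample_surface(ligand, probe, density)
    phi_lig = _coulomb_potential(surf.points, ligand.coords[lig_idx],
                                 ligand.charges(lig_idx))
    phi_env = _coulomb_potential(surf.points, environment.coords[env_idx],
                                 environment.charges(env_idx))
    return -_pearson(phi_lig, phi_env)


def flip_pose(ligand: Structure, axis: Sequence[float] = (1.0, 0.0, 0.0)) -> Structure:
    """The ligand rotated 180 degrees about ``axis`` through its center of mass."""
    from .geometry import center_of_mass

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    com = center_of_mass(ligand, "all")
    R = Rotation.from_rotvec(np.pi * axis).as_matrix()
    return ligand.with_coords((ligand.coords - com) @ R.T + com)


def score_pose(
    ligand: Structure,
    environment: Structure,
    probe: float = 1.4,
    decay_length: float = 2.0,
    density: float = 1.0,
) -> ComplementarityScore:
    """Both complementarity metrics for one pose (shared surface sampling)."""
    surf = sample_surface(ligand, probe, density)
    hydro = hydrophobic_match(ligand, environment, probe, decay_length,
                              density, surface=surf)
    try:
        elec = electrostatic_complementarity(ligand, environment, probe,
                                             density, surface=surf)
    except ValueError:
        elec = float("nan")
    return ComplementarityScore(hydro, elec, surf.n_points)


def rank_poses(
    poses: Sequence[tuple[str, Structure]],
    environment: Structure,
    sort_by: str = "hydrophobic_match",
    probe: float = 1.4,
    decay_length: float = 2.0,
    density: float = 1.0,
) -> pd.DataFrame:
    """Score and order candidate ligand poses against a shared environment.

    Use :func:`flip_pose` to build the 180-degree "reverted" counterpart of
    a pose for the flipped-pose comparison.
    """
    if len(poses) < 2:
        raise ValueError("rank_poses needs at least 2 poses")
    if sort_by not in {"hydrophobic_match", "electrostatic_complementarity"}:
        raise ValueError(f"unknown sort metric {sort_by!r}")
    rows = []
    for name, pose in poses:
        s = score_pose(pose, environment, probe, decay_length, density)
        rows.append({
            "pose": name,
            "hydrophobic_match": s.hydrophobic_match,
            "electrostatic_complementarity": s.electrostatic_complementarity,
            "n_points": s.n_points,
        })
    return (pd.DataFrame(rows)
            .sort_values(sort_by, ascending=False, kind="mergesort")
            .reset_index(drop=True))
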