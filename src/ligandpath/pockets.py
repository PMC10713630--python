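"""Grid-based internal-cavity detection with volume, lining, and polarity.

A probe-sized grid point is *empty* when it lies farther than
``vdW + probe`` from every atom, and *buried* when at least
``buriedness_min`` of 14 fixed ray directions (6 axial + 8 diagonal) hit
protein within ``ray_length``.  26-connected components of buried empty
points with at least ``min_points`` members are pockets, reported largest
first.  The method is fully deterministic — no alpha spheres, no sampling —
so volumes can be checked against analytic cavities.

Pocket polarity is the mean hydrophilicity of lining residues under a
chosen residue scale.  Bundled scales: a sign-flipped Kyte-Doolittle
(default; higher = more polar) and Wimley-White interface free energies
(kcal/mol; higher = more polar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "Pocket",
    "HydrophobicityScale",
    "KYTE_DOOLITTLE_POLARITY",
    "WIMLEY_WHITE_INTERFACE",
    "detect_pockets",
    "lining_residues",
    "polarity_score",
    "compare_homolog_pockets",
]

logger = logging.getLogger(__name__)

_KD_RAW = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue -> value map; ``higher_is_polar`` documents the orientation."""

    name: str
    values: dict[str, float]
    higher_is_polar: bool = True

    def __post_init__(self) -> None:
        missing = set(_KD_RAW) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues: {sorted(missing)}")

    def __getitem__(self, res_name: str) -> float:
        try:
            return self.values[res_name.upper()]
        except KeyError:
            raise KeyError(f"residue {res_name!r} not in scale {self.name}")


#: Kyte-Doolittle hydropathy, sign-flipped so higher = more polar (default).
KYTE_DOOLITTLE_POLARITY = HydrophobicityScale(
    name="kyte_doolittle_polarity",
    values={k: -v for k, v in _KD_RAW.items()},
)

#: Wimley-White interface transfer free energies (kcal/mol, higher = more polar).
WIMLEY_WHITE_INTERFACE = HydrophobicityScale(
    name="wimley_white_interface",
    values={
        "ALA": 0.17, "ARG": 0.81, "ASN": 0.42, "ASP": 1.23, "CYS": -0.24,
        "GLN": 0.58, "GLU": 2.02, "GLY": 0.01, "HIS": 0.96, "ILE": -0.31,
        "LEU": -0.56, "LYS": 0.99, "MET": -0.23, "PHE": -1.13, "PRO": 0.45,
        "SER": 0.13, "THR": 0.14, "TRP": -1.85, "TYR": -0.94, "VAL": 0.07,
    },
)

#: 6 axial + 8 diagonal ray directions (cheap isotropy).
_RAY_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
)
_RAY_DIRECTIONS /= np.linalg.norm(_RAY_DIRECTIONS, axis=1, keepdims=True)


@dataclass
class Pocket:
    """One detected cavity: its grid points, volume, centroid, and score inputs."""

    grid_points: np.ndarray
    spacing: float
    volume: float
    centroid: np.ndarray
    lining_residues: list[tuple[str, int, str]] = field(default_factory=list)
    polarity_score: float | None = None
    buriedness_threshold: int = 9

    @property
    def n_points(self) -> int:
        return self.grid_points.shape[0]


def detect_pockets(
    structure: Structure,
    spacing: float = 1.0,
    probe: float = 1.4,
    buriedness_min: int = 9,
    min_points: int = 30,
    ray_length: float = 12.0,
) -> list[Pocket]:
    """Detect buried cavities on a regular grid (largest volume first)."""
    heavy = structure.select("heavy")
    if heavy.size == 0:
        raise ValueError("structure has no heavy atoms")
    coords = structure.coords[heavy]
    radii = structure.radii(heavy)

    margin = 2.0 * spacing
    mins = coords.min(axis=0) - margin
    maxs = coords.max(axis=0) + margin
    axes = [np.arange(mins[k], maxs[k] + spacing, spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    # occupancy: within vdW + probe of any atom
    occupied = np.zeros(pts.shape[0], dtype=bool)
    tree = cKDTree(pts)
    for r in np.unique(radii):
        centers = coords[radii == r]
        for hits in tree.query_ball_point(centers, r=r + probe):
            occupied[hits] = True
    occ_grid = occupied.reshape(shape)

    empty_flat = np.nonzero(~occupied)[0]
    empty_pts = pts[empty_flat]

    # ray buriedness on the occupancy grid
    n_steps = int(np.ceil(ray_length / spacing))
    hit_count = np.zeros(empty_pts.shape[0], dtype=int)
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    for direction in _RAY_DIRECTIONS:
        hit = np.zeros(empty_pts.shape[0], dtype=bool)
        for step in range(1, n_steps + 1):
            probe_pts = empty_pts + direction * (step * spacing)
            idx = np.round((probe_pts - origin) / spacing).astype(int)
            inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
            sel = np.nonzero(inside & ~hit)[0]
            if sel.size == 0:
                break
            ii = idx[sel]
            hit[sel] |= occ_grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        hit_count += hit
    pocket_mask_flat = np.zeros(pts.shape[0], dtype=bool)
    pocket_mask_flat[empty_flat[hit_count >= buriedness_min]] = True
    pocket_grid = pocket_mask_flat.reshape(shape)

    labels, n_comp = ndimage.label(pocket_grid, structure=np.ones((3, 3, 3)))
    pockets: list[Pocket] = []
    for comp in range(1, n_comp + 1):
        member_idx = np.nonzero(labels.ravel() == comp)[0]
        if member_idx.size < min_points:
            continue
        gp = pts[member_idx]
        pockets.append(Pocket(
            grid_points=gp,
            spacing=spacing,
            volume=float(member_idx.size) * spacing ** 3,
            centroid=gp.mean(axis=0),
            buriedness_threshold=buriedness_min,
        ))
    pockets.sort(key=lambda p: p.volume, reverse=True)
    return pockets


def lining_residues(
    pocket: Pocket,
    structure: Structure,
    lining_cutoff: float = 4.5,
) -> list[tuple[str, int, str]]:
    """Residues with a heavy atom within ``lining_cutoff`` of any pocket point."""
    if lining_cutoff <= 0:
        return []
    heavy = structure.select("heavy")
    tree = cKDTree(structure.coords[heavy])
    hit_atoms: set[int] = set()
    for hits in cKDTree(pocket.grid_points).query_ball_tree(tree, r=lining_cutoff):
        hit_atoms.update(hits)
    keys = sorted({structure.atoms[heavy[i]].residue_key for i in hit_atoms},
                  key=lambda k: (k[0], k[1]))
    return [(c, r, structure.residue_name((c, r))) for c, r in keys]


def polarity_score(
    residues: Sequence[tuple[str, int, str]] | Sequence[str],
    scale: HydrophobicityScale = KYTE_DOOLITTLE_POLARITY,
) -> float:
    """Mean scale value over lining residues (higher = more polar by default)."""
    if len(residues) == 0:
        raise ValueError("polarity_score needs a non-empty residue list")
    names = [r if isinstance(r, str) else r[2] for r in residues]
    return float(np.mean([scale[n] for n in names]))


def compare_homolog_pockets(
    models: Sequence[tuple[str, Structure]],
    pocket_selector: str = "largest",
    scale: HydrophobicityScale = KYTE_DOOLITTLE_POLARITY,
    guide_point: np.ndarray | None = None,
    lining_cutoff: float = 4.5,
    **detect_kwargs,
) -> pd.DataFrame:
    """One pocket row (volume, polarity, lining) per homolog model.

    ``pocket_selector`` is ``largest`` or ``nearest_to_point`` (requires
    ``guide_point``, e.g. a mapped reference-ligand site; falls back to
    largest when no guide is given).  Models without any pocket get a row of
    missing values and a logged warning.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if pocket_selector not in {"largest", "nearest_to_point"}:
        raise ValueError(f"unknown pocket_selector {pocket_selector!r}")
    rows = []
    for name, model in models:
        pockets = detect_pockets(model, **detect_kwargs)
        if not pockets:
            logger.warning("model %s: no pocket detected", name)
            rows.append({"name": name, "volume": np.nan, "polarity": np.nan,
                         "n_lining": 0, "lining_residues": []})
            continue
        if pocket_selector == "nearest_to_point" and guide_point is not None:
            guide = np.asarray(guide_point, dtype=float)
            pocket = min(pockets, key=lambda p: np.linalg.norm(p.centroid - guide))
        else:
            pocket = pockets[0]
        lining = lining_residues(pocket, model, lining_cutoff)
        rows.append({
            "name": name,
            "volume": pocket.volume,
            "polarity": polarity_score(lining, scale) if lining else np.nan,
            "n_lining": len(lining),
            "lining_residues": lining,
        })
    return pd.DataFrame(rows)
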