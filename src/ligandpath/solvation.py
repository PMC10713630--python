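"""First-solvation-shell water counting and bulk normalization.

A water is in the first shell if any of its atoms lies within ``cutoff``
(default 3.0 A) of any ligand heavy atom; counts are per water residue.
Dividing by the mean shell count of the ligand free in bulk water gives the
solvation fraction — the desolvation readout that tracks a ligand's descent
into a buried, largely dehydrated cavity.  The fraction may exceed 1 (it is
a ratio of counts) and is never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import neighbor_pairs
from .structure import Structure, Trajectory

__all__ = [
    "SolvationSeries",
    "shell_count",
    "bulk_reference",
    "solvation_fraction",
]

DEFAULT_SHELL_CUTOFF = 3.0


@dataclass
class SolvationSeries:
    """Per-frame shell counts and bulk-normalized fractions."""

    shell_counts: np.ndarray
    fraction: np.ndarray
    bulk_mean: float
    cutoff: float

    def __post_init__(self) -> None:
        self.shell_counts = np.asarray(self.shell_counts, dtype=int)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.bulk_mean <= 0:
            raise ValueError("bulk_mean must be positive")


def shell_count(
    structure: Structure,
    frame: np.ndarray | None,
    ligand_selection,
    water_selection="water",
    cutoff: float = DEFAULT_SHELL_CUTOFF,
) -> int:
    """Number of distinct water residues with an atom within cutoff of the ligand.

    Only ligand heavy atoms count; ``frame`` optionally supplies trajectory
    coordinates for the structure's topology.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.coords if frame is None else np.asarray(frame, dtype=float)
    lig_idx = structure.select(ligand_selection)
    heavy = np.array([structure.atoms[i].element.upper() != "H" for i in lig_idx])
    lig_idx = lig_idx[heavy]
    if lig_idx.size == 0:
        raise ValueError("ligand selection has no heavy atoms")
    wat_idx = structure.select(water_selection)
    if wat_idx.size == 0:
        warnings.warn("empty water selection; shell count is 0", stacklevel=2)
        return 0
    pairs = neighbor_pairs(coords[lig_idx], coords[wat_idx], cutoff)
    residues = {structure.atoms[wat_idx[j]].residue_key for _, j, _ in pairs}
    return len(residues)


def bulk_reference(
    trajectory: Trajectory,
    ligand_selection,
    water_selection="water",
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    frames: np.ndarray | None = None,
) -> float:
    """Mean shell count over the frames of a bulk source.

    The source is either a dedicated ligand-in-water trajectory or the
    pre-contact stretch of a binding trajectory (pass ``frames``).  At least
    5 frames are required for a stable mean.
    """
    idx = np.arange(trajectory.n_frames) if frames is None else np.asarray(frames, int)
    if idx.size < 5:
        raise ValueError(f"bulk reference needs >= 5 frames, got {idx.size}")
    counts = [
        shell_count(trajectory.topology, trajectory.frames[f],
                    ligand_selection, water_selection, cutoff)
        for f in idx
    ]
    return float(np.mean(counts))


def solvation_fraction(
    trajectory: Trajectory,
    ligand_selection,
    water_selection="water",
    bulk_mean: float = None,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
) -> SolvationSeries:
    """Per-frame shell counts normalized by a bulk mean."""
    if bulk_mean is None or bulk_mean <= 0:
        raise ValueError("bulk_mean must be a positive number")
    counts = np.array([
        shell_count(trajectory.topology, trajectory.frames[f],
                    ligand_selection, water_selection, cutoff)
        for f in range(trajectory.n_frames)
    ])
    return SolvationSeries(
        shell_counts=counts,
        fraction=counts / bulk_mean,
        bulk_mean=float(bulk_mean),
        cutoff=cutoff,
    )
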