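"""Ligand-residue contact detection and frequency statistics.

A residue is in contact in a frame when at least one of its heavy atoms lies
within ``cutoff`` (default 4.0 A) of at least one ligand heavy atom — a
transparent single-distance criterion standing in for interaction-type-
specific geometric rules.  Frequencies are fractions of frames in contact;
cohort averages are taken over entry trajectories only, matching how
ingress interactions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import neighbor_pairs
from .structure import Structure, Trajectory

__all__ = [
    "ContactTable",
    "frame_contacts",
    "contact_frequencies",
    "cohort_frequencies",
]

DEFAULT_CONTACT_CUTOFF = 4.0


@dataclass
class ContactTable:
    """Residue x frame contact booleans plus per-residue frequencies.

    ``residues`` carries (chain, res_id, res_name) in topology order for
    every residue that was ever in contact; ``window`` is the frame range
    the frequencies were averaged over.
    """

    residues: list[tuple[str, int, str]]
    matrix: np.ndarray          # (n_residues, n_window_frames) bool
    frequencies: pd.Series      # index: (chain, res_id)
    window: tuple[int, int]

    def frequency(self, chain: str, res_id: int) -> float:
        return float(self.frequencies.get((chain, res_id), 0.0))


def frame_contacts(
    structure: Structure,
    frame: np.ndarray | None,
    ligand_selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    receptor_selection: str = "protein and not chain L",
) -> set[tuple[str, int]]:
    """Residue keys with a heavy atom within cutoff of a ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.coords if frame is None else np.asarray(frame, dtype=float)
    lig_idx = structure.select(ligand_selection)
    lig_idx = lig_idx[[structure.atoms[i].element.upper() != "H" for i in lig_idx]]
    lig_set = set(int(i) for i in lig_idx)
    rec_idx = structure.select(receptor_selection)
    rec_idx = np.array([
        i for i in rec_idx
        if structure.atoms[i].element.upper() != "H" and int(i) not in lig_set
    ], dtype=int)
    if lig_idx.size == 0 or rec_idx.size == 0:
        return set()
    pairs = neighbor_pairs(coords[lig_idx], coords[rec_idx], cutoff)
    return {structure.atoms[rec_idx[j]].residue_key for _, j, _ in pairs}


def contact_frequencies(
    trajectory: Trajectory,
    ligand_selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    window: tuple[int, int] | str = "after_first_contact",
    receptor_selection: str = "protein and not chain L",
) -> ContactTable:
    """Per-residue contact frequency over a frame window.

    ``window`` is an explicit ``(start, stop)`` range, ``"all"``, or
    ``"after_first_contact"`` (default): the denominator starts at the first
    frame with any receptor contact, so bulk-diffusion frames do not dilute
    ingress frequencies with trajectory length.
    """
    top = trajectory.topology
    n = trajectory.n_frames
    per_frame: list[set[tuple[str, int]]] = [
        frame_contacts(top, trajectory.frames[f], ligand_selection, cutoff,
                       receptor_selection)
        for f in range(n)
    ]
    if window == "all":
        start, stop = 0, n
    elif window == "after_first_contact":
        start = next((f for f, s in enumerate(per_frame) if s), n)
        stop = n
        if start == n:
            raise ValueError("trajectory has no receptor contact in any frame")
    else:
        start, stop = int(window[0]), int(window[1])
        if not (0 <= start < stop <= n):
            raise ValueError(f"empty or invalid window {window!r} for {n} frames")

    keys_order = [k for k in top.residue_keys()
                  if any(k in per_frame[f] for f in range(start, stop))]
    matrix = np.zeros((len(keys_order), stop - start), dtype=bool)
    for col, f in enumerate(range(start, stop)):
        for row, key in enumerate(keys_order):
            matrix[row, col] = key in per_frame[f]
    freqs = pd.Series(
        matrix.mean(axis=1) if keys_order else [],
        index=pd.Index(keys_order, tupleize_cols=False),
        dtype=float,
    )
    residues = [(c, r, top.residue_name((c, r))) for c, r in keys_order]
    return ContactTable(
        residues=residues, matrix=matrix, frequencies=freqs,
        window=(start, stop),
    )


def cohort_frequencies(
    tables: Sequence[ContactTable],
    entry_mask: Sequence[bool],
) -> pd.Series:
    """Unweighted mean frequency per residue over entry trajectories.

    The residue universe is the outer join of the selected tables; a residue
    missing from one table contributes 0 there.
    """
    if len(tables) != len(entry_mask):
        raise ValueError("tables and entry_mask must have equal length")
    selected = [t for t, m in zip(tables, entry_mask) if m]
    if not selected:
        raise ValueError("no entry trajectories selected")
    keys: list[tuple[str, int]] = []
    for t in selected:
        for k in t.frequencies.index:
            if k not in keys:
                keys.append(k)
    out = pd.Series(0.0, index=pd.Index(keys, tupleize_cols=False))
    for t in selected:
        for k in keys:
            out[k] += float(t.frequencies.get(k, 0.0))
    return out / len(selected)
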