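"""Alignment-based conservation statistics.

Per-column composition, consensus-logo matrices, and pairwise pocket
identity/similarity percentages — the sequence-level readouts used to ask
whether a binding pocket or translocation pathway is conserved across a
receptor family.

The similarity convention is a configurable residue grouping (defaults
below); identity pairs count as within-group, so identity <= similarity
always.  Columns where either sequence of a pair is gapped are excluded
from the pairwise denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, Alignment

__all__ = [
    "DEFAULT_SIMILARITY_GROUPS",
    "residue_group",
    "ColumnStats",
    "PocketConservation",
    "column_stats",
    "pocket_identity",
    "logo_matrix",
]

#: Default physicochemical similarity groups (one-letter codes).
DEFAULT_SIMILARITY_GROUPS: tuple[str, ...] = (
    "AVLIMC", "FWY", "ST", "KRH", "DE", "NQ", "G", "P",
)

GAP = "-"


def residue_group(residue: str, groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS) -> str | None:
    """The similarity group containing ``residue``, or None (gap/X/unknown)."""
    for g in groups:
        if residue in g:
            return g
    return None


@dataclass
class ColumnStats:
    """Residue composition of selected alignment columns.

    ``counts`` and ``frequencies`` are position x residue tables over non-gap
    symbols; ``consensus`` is the modal residue per column (ties broken
    alphabetically); ``gap_fraction`` is the fraction of gapped rows.
    Positions whose column is entirely gaps are listed in ``all_gap_positions``
    (their frequency rows are zero, never silently dropped).
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    consensus: pd.Series
    gap_fraction: pd.Series
    all_gap_positions: list[int] = field(default_factory=list)


def column_stats(alignment: Alignment, positions: Sequence[int] | None = None) -> ColumnStats:
    """Counts, frequencies, consensus, and gap fraction per column."""
    if positions is None:
        positions = range(alignment.length)
    positions = [int(p) for p in positions]
    if any(p < 0 or p >= alignment.length for p in positions):
        raise ValueError("position out of alignment range")
    residues = list(AMINO_ACIDS) + ["X"]
    counts = pd.DataFrame(0, index=positions, columns=residues, dtype=int)
    gap_fraction = pd.Series(0.0, index=positions)
    consensus: dict[int, str] = {}
    all_gap: list[int] = []
    n = alignment.n_sequences
    for p in positions:
        col = alignment.column(p)
        gaps = col.count(GAP)
        gap_fraction[p] = gaps / n
        for sym in col:
            if sym != GAP:
                counts.loc[p, sym] += 1
        if gaps == n:
            all_gap.append(p)
            consensus[p] = GAP
        else:
            row = counts.loc[p]
            consensus[p] = min(row.index[row == row.max()])  # alphabetical ties
    totals = counts.sum(axis=1).replace(0, 1)
    frequencies = counts.div(totals, axis=0)
    return ColumnStats(
        counts=counts,
        frequencies=frequencies,
        consensus=pd.Series(consensus),
        gap_fraction=gap_fraction,
        all_gap_positions=all_gap,
    )


@dataclass
class PocketConservation:
    """Pairwise identity/similarity percentages over pocket positions."""

    positions: list[int]
    identity_pct: float
    similarity_pct: float
    pair: tuple[str, str]
    n_compared: int
    n_excluded_gapped: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= self.similarity_pct <= 100.0):
            raise ValueError("need 0 <= identity <= similarity <= 100")


def pocket_identity(
    alignment: Alignment,
    idA: str,
    idB: str,
    positions: Sequence[int],
    similarity_groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
) -> PocketConservation:
    """Identity and similarity (%) between two sequences over pocket columns.

    Identity is the fraction of compared columns with the same residue;
    similarity the fraction in the same physicochemical group (identical
    residues included).  Columns where either sequence is gapped are dropped
    from the denominator.
    """
    for sid in (idA, idB):
        if sid not in alignment.sequences:
            raise KeyError(f"sequence id {sid!r} not in alignment")
    a = alignment.sequences[idA]
    b = alignment.sequences[idB]
    positions = [int(p) for p in positions]
    if any(p < 0 or p >= alignment.length for p in positions):
        raise ValueError("position out of alignment range")
    matches = similar = compared = excluded = 0
    for p in positions:
        ra, rb = a[p], b[p]
        if ra == GAP or rb == GAP:
            excluded += 1
            continue
        compared += 1
        if ra == rb:
            matches += 1
            similar += 1
        else:
            ga = residue_group(ra, similarity_groups)
            gb = residue_group(rb, similarity_groups)
            if ga is not None and ga == gb:
                similar += 1
    if compared == 0:
        raise ValueError("no comparable (non-gap) positions for this pair")
    return PocketConservation(
        positions=positions,
        identity_pct=100.0 * matches / compared,
        similarity_pct=100.0 * similar / compared,
        pair=(idA, idB),
        n_compared=compared,
        n_excluded_gapped=excluded,
    )


def logo_matrix(
    alignment: Alignment,
    positions: Sequence[int] | None = None,
    units: str = "probability",
) -> pd.DataFrame:
    """Position x residue logo matrix in probability or bit units.

    In ``bits``, each row is p * IC with IC = log2(20) - H(column), the
    information content of the column over the 20-residue alphabet (gaps
    excluded).
    """
    if units not in {"probability", "bits"}:
        raise ValueError("units must be 'probability' or 'bits'")
    stats = column_stats(alignment, positions)
    probs = stats.frequencies[list(AMINO_ACIDS)]
    # renormalize over the 20 canonical residues (drops X mass if any)
    totals = probs.sum(axis=1).replace(0, 1)
    probs = probs.div(totals, axis=0)
    if units == "probability":
        return probs
    max_bits = math.log2(20)
    out = probs.copy()
    for p in probs.index:
        row = probs.loc[p].to_numpy()
        nz = row[row > 0]
        entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else max_bits
        out.loc[p] = row * (max_bits - entropy)
    return out
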