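"""Core molecular containers: atoms, structures, trajectories.

Conventions used throughout the package:

* coordinates are in Angstrom,
* residue numbering is 1-based PDB numbering and is never rewritten on read,
* a residue is keyed by ``(chain, res_id)``,
* heavy atoms are all atoms whose element is not hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "WATER_RES_NAMES",
    "infer_element",
]

#: Standard atomic masses (u) for the elements that occur in biomolecular files.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971,
}

#: Fallback van der Waals radii (A) by element, used when the input format
#: carries no radius column (plain PDB).
VDW_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.52, "MN": 1.39,
    "CU": 1.40, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

#: Residue names recognized as water (common MD output conventions).
WATER_RES_NAMES: frozenset[str] = frozenset({"HOH", "WAT", "TIP3"})

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE", "CA",
}


def infer_element(name: str, res_name: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Follows PDB naming conventions: leading digits are stripped, two-letter
    ion/halogen symbols are recognized, everything else maps to its first
    alphabetic character.  Calcium ("CA" the ion) is only inferred when the
    residue name says so; an atom named CA in an amino acid is a carbon.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER_ELEMENTS:
        if upper[:2] == "CA" and res_name.strip().upper() not in {"CA", "CAL"}:
            return "C"
        return upper[:2]
    return upper[0]


@dataclass
class Atom:
    """One atom with PDB-style identity and optional charge/radius.

    ``charge`` is in elementary charges, ``radius`` in Angstrom; both are
    populated by PQR input (or by generators) and ``None`` otherwise.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coord: np.ndarray
    charge: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial} has non-positive radius")
        if self.res_id < 1:
            raise ValueError(
                f"atom {self.serial}: res_id must be >= 1 (got {self.res_id})"
            )

    @property
    def vdw_radius(self) -> float:
        """Radius from the file when present, else the element fallback table."""
        if self.radius is not None:
            return self.radius
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW_RADIUS)

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element.upper()]
        except KeyError:
            raise KeyError(f"no standard atomic mass for element {self.element!r}")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_id)


class Structure:
    """An ordered collection of atoms with a residue index.

    Atom order is stable and is the order of every per-atom array
    (:attr:`coords`, :meth:`masses`, ...).  ``metadata`` is a free-form dict
    used e.g. by the synthetic generators to record planted geometry.
    """

    def __init__(self, atoms: Sequence[Atom], metadata: Mapping | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.metadata: dict = dict(metadata or {})
        self._residue_index: dict[tuple[str, int], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._residue_index.setdefault(atom.residue_key, []).append(i)
        self._coords: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array; a shared cache, do not mutate in place."""
        if self._coords is None:
            if self.atoms:
                self._coords = np.array([a.coord for a in self.atoms], dtype=float)
            else:
                self._coords = np.empty((0, 3), dtype=float)
        return self._coords

    @property
    def residue_index(self) -> dict[tuple[str, int], list[int]]:
        return self._residue_index

    def residue_keys(self) -> list[tuple[str, int]]:
        return list(self._residue_index)

    def residue_name(self, key: tuple[str, int]) -> str:
        return self.atoms[self._residue_index[key][0]].res_name

    def residues(self) -> Iterator[tuple[tuple[str, int], list[int]]]:
        return iter(self._residue_index.items())

    def masses(self, indices: np.ndarray | None = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.mass for a in atoms], dtype=float)

    def radii(self, indices: np.ndarray | None = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.vdw_radius for a in atoms], dtype=float)

    def charges(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Per-atom charges; raises if any requested atom has none."""
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        out = np.empty(len(atoms), dtype=float)
        for k, a in enumerate(atoms):
            if a.charge is None:
                raise ValueError(
                    f"atom {a.serial} ({a.name} {a.res_name}{a.res_id}) has no charge"
                )
            out[k] = a.charge
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A new Structure with the same atom metadata and replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.res_name, a.res_id, a.chain,
                 coords[i].copy(), a.charge, a.radius)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, metadata=self.metadata)

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices], metadata=self.metadata)

    # -- selection ---------------------------------------------------------
    def select(self, selection) -> np.ndarray:
        """Resolve a selection to an index array.

        Accepts an index array/list (returned as-is after validation) or a
        small selection-string language: clauses joined by ``and``, each
        clause one of ``chain A``, ``resname HOH WAT``, ``name CA``,
        ``element C``, ``resid 5`` / ``resid 5:10``, or the bare keywords
        ``water``, ``protein`` (= not water), ``heavy`` (= not hydrogen),
        ``all``.  A clause may be prefixed by ``not``.
        """
        if isinstance(selection, str):
            mask = self._select_str(selection)
            return np.nonzero(mask)[0]
        idx = np.asarray(selection, dtype=int)
        if idx.ndim != 1:
            raise ValueError("index selection must be one-dimensional")
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise IndexError("selection index out of range")
        return idx

    def _clause_mask(self, clause: str) -> np.ndarray:
        tokens = clause.split()
        negate = False
        while tokens and tokens[0] == "not":
            negate = not negate
            tokens = tokens[1:]
        if not tokens:
            raise ValueError(f"empty selection clause in {clause!r}")
        key, args = tokens[0], tokens[1:]
        n = self.n_atoms
        if key == "all":
            mask = np.ones(n, dtype=bool)
        elif key == "water":
            names = self.metadata.get("water_res_names", WATER_RES_NAMES)
            mask = np.array([a.res_name in names for a in self.atoms])
        elif key == "protein":
            names = self.metadata.get("water_res_names", WATER_RES_NAMES)
            mask = np.array([a.res_name not in names for a in self.atoms])
        elif key == "heavy":
            mask = np.array([a.element.upper() != "H" for a in self.atoms])
        elif key == "chain":
            mask = np.array([a.chain in args for a in self.atoms])
        elif key == "resname":
            mask = np.array([a.res_name in args for a in self.atoms])
        elif key == "name":
            mask = np.array([a.name in args for a in self.atoms])
        elif key == "element":
            allowed = {x.upper() for x in args}
            mask = np.array([a.element.upper() in allowed for a in self.atoms])
        elif key == "resid":
            ids: set[int] = set()
            for arg in args:
                if ":" in arg:
                    lo, hi = arg.split(":")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(arg))
            mask = np.array([a.res_id in ids for a in self.atoms])
        else:
            raise ValueError(f"unknown selection keyword {key!r}")
        return ~mask if negate else mask

    def _select_str(self, expr: str) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expr.split(" and "):
            mask &= self._clause_mask(clause.strip())
        return mask


class Trajectory:
    """Ordered coordinate frames bound to one :class:`Structure` topology.

    ``frame_interval`` is user metadata (ns per frame); nothing in the
    analysis depends on it.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray | Sequence[np.ndarray],
        frame_interval: float | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError(f"frames must be (n_frames, n_atoms, 3), got {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {frames.shape[1]} != topology atom count "
                f"{topology.n_atoms}"
            )
        self.topology = topology
        self.frames = frames
        self.frame_interval = frame_interval

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def frame_structure(self, i: int) -> Structure:
        """The topology with frame ``i`` coordinates, as a Structure."""
        return self.topology.with_coords(self.frames[i])

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)
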