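"""Readers and writers for structures, trajectories, and alignments.

PDB, PQR, and multi-model PDB are parsed natively (fixed-column for PDB,
whitespace-delimited for PQR) so that the whole test surface is plain text.
DCD reading is delegated to MDAnalysis when available.  Alignments are read
through Biopython with package-side validation of the contracts (unique ids,
equal gapped lengths).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .structure import Atom, Structure, Trajectory, infer_element

__all__ = [
    "ParseError",
    "Alignment",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_alignment",
    "write_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS + "X-")


class ParseError(ValueError):
    """A structure/alignment file violated its format contract."""


# ---------------------------------------------------------------------------
# PDB / PQR structures
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, line_no: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_id = int(line[22:26])
        coord = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {line_no}: {line.rstrip()!r}") from exc
    if not element:
        element = infer_element(name, res_name)
    return Atom(serial, name, element, res_name, res_id, chain, np.asarray(coord))


def _parse_pqr_atom_line(line: str, line_no: int) -> Atom:
    fields = line.split()
    # ATOM serial name resName [chain] resId x y z charge radius
    try:
        if len(fields) == 11:
            (_, serial, name, res_name, chain, res_id,
             x, y, z, charge, radius) = fields
        elif len(fields) == 10:
            (_, serial, name, res_name, res_id,
             x, y, z, charge, radius) = fields
            chain = "A"
        else:
            raise ValueError(f"{len(fields)} fields")
        atom = Atom(
            int(serial), name, infer_element(name, res_name), res_name,
            int(res_id), chain, np.array([float(x), float(y), float(z)]),
            charge=float(charge), radius=float(radius),
        )
    except ValueError as exc:
        raise ParseError(f"malformed PQR ATOM record at line {line_no}: {line.rstrip()!r}") from exc
    return atom


def _infer_structure_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {"pqr": "pqr"}.get(ext.lstrip("."), "pdb")


def read_structure(path: str, format: str | None = None) -> Structure:
    """Read a PDB or PQR file into a :class:`Structure`.

    Atoms are kept in file order.  For multi-model PDB files only the first
    model is read (use :func:`read_trajectory` for the rest).  A duplicate
    ``(chain, res_id, name)`` triple is an error.
    """
    fmt = format or _infer_structure_format(path)
    if fmt not in {"pdb", "pqr"}:
        raise ValueError(f"unknown structure format {fmt!r}")
    atoms: list[Atom] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if fmt == "pdb":
                record = line[:6].strip()
            else:  # PQR is whitespace-delimited
                record = line.split(None, 1)[0] if line.strip() else ""
            if record == "ENDMDL":
                break
            if record not in {"ATOM", "HETATM"}:
                continue
            if fmt == "pdb":
                atom = _parse_pdb_atom_line(line, line_no)
            else:
                atom = _parse_pqr_atom_line(line, line_no)
            key = (atom.chain, atom.res_id, atom.name)
            if key in seen:
                raise ParseError(
                    f"duplicate atom (chain={atom.chain!r}, res_id={atom.res_id}, "
                    f"name={atom.name!r}) at line {line_no}"
                )
            seen.add(key)
            atoms.append(atom)
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records found in {path}")
    return Structure(atoms)


def _format_pdb_atom_line(atom: Atom, coord: np.ndarray) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {atom.serial % 100000:5d} {name:<4.4s} {atom.res_name:<3.3s} "
        f"{atom.chain[:1]}{atom.res_id % 10000:4d}    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
    )


def write_structure(path: str, structure: Structure, format: str = "pdb") -> None:
    """Write a Structure as PDB (3-decimal coordinates) or PQR."""
    if format not in {"pdb", "pqr"}:
        raise ValueError(f"unknown structure format {format!r}")
    with open(path, "w") as fh:
        for atom in structure.atoms:
            if format == "pdb":
                fh.write(_format_pdb_atom_line(atom, atom.coord) + "\n")
            else:
                charge = 0.0 if atom.charge is None else atom.charge
                fh.write(
                    f"ATOM {atom.serial} {atom.name} {atom.res_name} {atom.chain} "
                    f"{atom.res_id} {atom.coord[0]:.3f} {atom.coord[1]:.3f} "
                    f"{atom.coord[2]:.3f} {charge:.4f} {atom.vdw_radius:.4f}\n"
                )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str,
    topology: Structure,
    format: str | None = None,
    skip_frames: int = 0,
) -> Trajectory:
    """Read a coordinate series against a fixed topology.

    ``skip_frames`` drops the leading frames (e.g. an equilibration stretch)
    before the trajectory is built.  Every frame must carry exactly one
    coordinate per topology atom.
    """
    fmt = format
    if fmt is None:
        fmt = "dcd" if path.lower().endswith(".dcd") else "multi_model_pdb"
    if fmt == "multi_model_pdb":
        frames = _read_multi_model_pdb_frames(path, topology.n_atoms)
    elif fmt == "dcd":
        frames = _read_dcd_frames(path, topology.n_atoms)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if skip_frames < 0:
        raise ValueError("skip_frames must be >= 0")
    if skip_frames >= len(frames):
        raise ValueError(
            f"skip_frames={skip_frames} leaves no frames (file has {len(frames)})"
        )
    return Trajectory(topology, np.asarray(frames)[skip_frames:])


def _read_multi_model_pdb_frames(path: str, n_atoms: int) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    saw_model = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                current = []
            elif record in {"ATOM", "HETATM"}:
                if current is None:
                    current = []  # tolerate model-less single-frame files
                atom = _parse_pdb_atom_line(line, line_no)
                current.append(atom.coord.tolist())
            elif record == "ENDMDL":
                if current is None:
                    raise ParseError(f"ENDMDL without MODEL at line {line_no}")
                _check_frame(current, len(frames), n_atoms)
                frames.append(np.asarray(current))
                current = None
    if current:  # trailing frame without ENDMDL
        _check_frame(current, len(frames), n_atoms)
        frames.append(np.asarray(current))
    if not frames:
        raise ParseError(f"no coordinate frames found in {path}")
    return frames


def _check_frame(coords: list, frame_idx: int, n_atoms: int) -> None:
    if len(coords) != n_atoms:
        raise ParseError(
            f"frame {frame_idx}: {len(coords)} atoms, topology has {n_atoms}"
        )


def _read_dcd_frames(path: str, n_atoms: int) -> list[np.ndarray]:
    try:
        from MDAnalysis.coordinates.DCD import DCDReader
    except ImportError as exc:  # pragma: no cover
        raise ImportError("DCD reading requires MDAnalysis") from exc
    reader = DCDReader(path)
    frames = [np.array(ts.positions, dtype=float) for ts in reader]
    for i, f in enumerate(frames):
        if f.shape[0] != n_atoms:
            raise ParseError(f"frame {i}: {f.shape[0]} atoms, topology has {n_atoms}")
    return frames


def write_trajectory(path: str, trajectory: Trajectory, format: str = "multi_model_pdb") -> None:
    """Write a trajectory as a multi-model PDB (3-decimal coordinates)."""
    if format != "multi_model_pdb":
        raise ValueError("only multi_model_pdb output is supported")
    top = trajectory.topology
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for atom, coord in zip(top.atoms, frame):
                fh.write(_format_pdb_atom_line(atom, coord) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A gapped multiple sequence alignment (20 amino acids + gap + X)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        lengths = {sid: len(s) for sid, s in self.sequences.items()}
        distinct = set(lengths.values())
        if len(distinct) > 1:
            mode = max(distinct, key=lambda L: sum(v == L for v in lengths.values()))
            bad = sorted(sid for sid, L in lengths.items() if L != mode)
            raise ParseError(f"unequal gapped lengths for sequences: {', '.join(bad)}")
        for sid, seq in self.sequences.items():
            extra = set(seq.upper()) - ALIGNMENT_ALPHABET
            if extra:
                raise ParseError(
                    f"sequence {sid!r} contains invalid symbols: {sorted(extra)}"
                )
            self.sequences[sid] = seq.upper()

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, position: int) -> str:
        """The alignment column at 0-based ``position``."""
        return "".join(seq[position] for seq in self.sequences.values())


def read_alignment(path: str, format: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment. Duplicate ids and ragged rows are errors."""
    fmt = format
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = "clustal" if ext in {"aln", "clustal", "clw"} else "fasta"
    if fmt not in {"fasta", "clustal"}:
        raise ValueError(f"unknown alignment format {fmt!r}")
    sequences: dict[str, str] = {}
    if fmt == "fasta":
        from Bio import SeqIO
        for record in SeqIO.parse(path, "fasta"):
            if record.id in sequences:
                raise ParseError(f"duplicate sequence id {record.id!r}")
            sequences[record.id] = str(record.seq)
    else:
        from Bio import AlignIO
        for record in AlignIO.read(path, "clustal"):
            if record.id in sequences:
                raise ParseError(f"duplicate sequence id {record.id!r}")
            sequences[record.id] = str(record.seq)
    if not sequences:
        raise ParseError(f"no sequences found in {path}")
    return Alignment(sequences)


def write_alignment(path: str, alignment: Alignment, format: str = "fasta") -> None:
    if format != "fasta":
        raise ValueError("only fasta output is supported")
    with open(path, "w") as fh:
        for sid, seq in alignment.sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
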