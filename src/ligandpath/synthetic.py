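"""Synthetic study systems with machine-readable ground truth.

This module generates every input class the pipeline consumes:

* a toy receptor — a closed pseudo-atom shell enclosing a spherical cavity
  reached through a carved channel (a stand-in for a 7TM receptor with a
  buried ligand-binding pocket),
* ligand translocation trajectories with planted metastable dwell states at
  prescribed site distances, optional explicit single-particle waters, and
  planted first-shell occupancy per state,
* cohorts of such trajectories with planted vestibule-entry / full-binding
  counts,
* a ligand-in-bulk-water box for solvation normalization,
* gapless alignments with constructively planted pairwise identity and
  similarity over designated columns,
* tiny charge/hydrophobicity-decorated ligand-environment complexes whose
  complementarity sign is known by construction.

Ground truth (contact schedules, shell counts) is recomputed from the
emitted coordinates by a direct numpy distance pass, so downstream analyses
are tested against geometry rather than against sampling intent.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import DEFAULT_SIMILARITY_GROUPS, residue_group
from .io import AMINO_ACIDS, Alignment
from .structure import Atom, Structure, Trajectory

__all__ = [
    "STATE_ORDER",
    "TranslocationTruth",
    "CohortTruth",
    "ColumnIdentityPlan",
    "make_toy_receptor",
    "make_translocation_trajectory",
    "make_contact_schedule_trajectory",
    "make_cohort",
    "make_bulk_water_system",
    "make_alignment",
    "make_complementarity_case",
]

#: Ingress order of the planted metastable states.
STATE_ORDER = ("bulk", "contact", "entry", "vestibule", "binding")

#: Default planted mean site distances (A) per state, mimicking the staged
#: approach of an agonist from solvent to a buried cavity.
DEFAULT_PLANTED_DISTANCES = {
    "bulk": 40.0, "contact": 25.0, "entry": 15.0, "vestibule": 8.0, "binding": 2.0,
}

#: Default planted first-shell occupancy per state as a fraction of the bulk
#: shell count: stable ~50% while the ligand sits at the entry/vestibule and
#: ~20% once bound, with full solvation in bulk.
DEFAULT_SOLVATION_PLAN = {
    "bulk": 1.0, "contact": 0.8, "entry": 0.5, "vestibule": 0.5, "binding": 0.2,
}

#: Liquid-water number density (waters per A^3).
BULK_WATER_DENSITY = 0.0334

_WALL_CLEARANCE = 1.7 + 1.4  # carbon vdW + water probe: empty-space clearance


@dataclass
class TranslocationTruth:
    """Planted ground truth for one translocation trajectory."""

    state_schedule: list[str]
    planted_distances: dict[str, float]
    contact_schedule: dict[tuple[str, int], frozenset[int]]
    entered_vestibule: bool
    fully_bound: bool
    seed: int
    bulk_shell_count: int | None = None
    solvation_plan: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "state_schedule": self.state_schedule,
            "planted_distances": self.planted_distances,
            "contact_schedule": {
                f"{c}:{r}": sorted(fr) for (c, r), fr in self.contact_schedule.items()
            },
            "entered_vestibule": self.entered_vestibule,
            "fully_bound": self.fully_bound,
            "seed": self.seed,
            "bulk_shell_count": self.bulk_shell_count,
            "solvation_plan": self.solvation_plan,
        }


@dataclass
class CohortTruth:
    """Planted ground truth for a cohort of translocation trajectories."""

    n_trajectories: int
    n_vestibule_entries: int
    n_full_bindings: int
    trajectories: list[TranslocationTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.n_full_bindings <= self.n_vestibule_entries
                <= self.n_trajectories):
            raise ValueError(
                "cohort counts must satisfy full <= vestibule <= total"
            )

    def to_dict(self) -> dict:
        return {
            "n_trajectories": self.n_trajectories,
            "n_vestibule_entries": self.n_vestibule_entries,
            "n_full_bindings": self.n_full_bindings,
            "trajectories": [t.to_dict() for t in self.trajectories],
        }


# ---------------------------------------------------------------------------
# Toy receptor
# ---------------------------------------------------------------------------

def make_toy_receptor(
    n_residues: int = 1500,
    cavity_center: Sequence[float] = (0.0, 0.0, 0.0),
    cavity_radius: float = 5.0,
    channel_axis: Sequence[float] = (0.0, 0.0, 1.0),
    seed: int = 0,
    res_name_cycle: Sequence[str] = ("ALA",),
    atom_density: float = 0.125,
    channel_radius: float = 3.0,
) -> Structure:
    """A closed pseudo-atom shell with an internal spherical cavity.

    Single-carbon pseudo-residues are placed uniformly in a spherical shell
    whose inner radius leaves exactly ``cavity_radius`` of probe-accessible
    empty space around ``cavity_center``.  A cylinder of radius
    ``channel_radius`` along ``+channel_axis`` is kept free of atoms,
    emulating the transient entry channel.  Residue names cycle through
    ``res_name_cycle`` (used to plant pocket-lining compositions).
    """
    if cavity_radius <= 0:
        raise ValueError("cavity_radius must be positive")
    center = np.asarray(cavity_center, dtype=float)
    axis = np.asarray(channel_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r_in = cavity_radius + _WALL_CLEARANCE

    # Dense deterministic wall layer at r_in so the probe-accessible empty
    # region around the center is a crisp sphere of radius cavity_radius.
    wall_spacing = 1.2
    n_wall_full = int(np.ceil(4.0 * np.pi * r_in ** 2 / wall_spacing ** 2))
    k = np.arange(n_wall_full)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_wall_full
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, 1.0))
    wall = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1) * r_in
    t_ax = wall @ axis
    perp = np.linalg.norm(wall - t_ax[:, None] * axis, axis=1)
    wall = wall[~((t_ax > 0) & (perp < channel_radius))] + center

    n_body = n_residues - wall.shape[0]
    if n_body < n_wall_full // 3:
        raise ValueError(
            "cavity too large for the shell: too few residues to enclose it"
        )
    r_out = (r_in ** 3 + 3.0 * n_body / (4.0 * np.pi * atom_density)) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = [p for p in wall]
    while len(coords) < n_residues:
        m = 2 * (n_residues - len(coords)) + 16
        d = rng.normal(size=(m, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = (r_in ** 3 + rng.random(m) * (r_out ** 3 - r_in ** 3)) ** (1.0 / 3.0)
        pts = center + d * r[:, None]
        rel = pts - center
        t_ax = rel @ axis
        perp = np.linalg.norm(rel - t_ax[:, None] * axis, axis=1)
        keep = ~((t_ax > 0) & (perp < channel_radius))
        for p in pts[keep]:
            if len(coords) < n_residues:
                coords.append(p)
    atoms = [
        Atom(i + 1, "CA", "C", res_name_cycle[i % len(res_name_cycle)],
             i + 1, "A", coords[i])
        for i in range(n_residues)
    ]
    meta = {
        "cavity_center": center.tolist(),
        "cavity_radius": cavity_radius,
        "channel_axis": axis.tolist(),
        "shell_inner_radius": r_in,
        "shell_outer_radius": r_out,
        "n_wall_residues": wall.shape[0],  # wall atoms come first in atom order
        "seed": seed,
    }
    return Structure(atoms, metadata=meta)


# ---------------------------------------------------------------------------
# Ligand and water helpers
# ---------------------------------------------------------------------------

def _make_ligand_template(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """A rigid all-carbon blob with an exactly zero center of mass.

    The spatial scale grows as n^(1/3) so atom density stays molecule-like
    and the first-shell volume scales with size.
    """
    scale = 0.8 * n_atoms ** (1.0 / 3.0)
    coords = rng.normal(scale=scale, size=(n_atoms, 3))
    return coords - coords.mean(axis=0)


def _ligand_atoms(template: np.ndarray, serial_start: int) -> list[Atom]:
    return [
        Atom(serial_start + i, f"C{i + 1}", "C", "LIG", 1, "L", template[i])
        for i in range(template.shape[0])
    ]


def _grid_volume(template: np.ndarray, lo: float, hi: float, spacing: float = 0.35) -> float:
    """Volume of {x : lo < min-dist(x, atoms) <= hi} by grid counting."""
    pad = hi + spacing
    mins = template.min(axis=0) - pad
    maxs = template.max(axis=0) + pad
    axes = [np.arange(mins[k], maxs[k] + spacing, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d = np.sqrt(((pts[:, None, :] - template[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return float(((d > lo) & (d <= hi)).sum()) * spacing ** 3


def _sample_shell_waters(
    ligand_coords: np.ndarray,
    n: int,
    rng: np.random.Generator,
    inner: float = 1.7,
    outer: float = 3.0,
) -> np.ndarray:
    """Water positions with min ligand-atom distance in (inner, outer]."""
    out = np.empty((n, 3))
    got = 0
    n_atoms = ligand_coords.shape[0]
    while got < n:
        k = int(rng.integers(n_atoms))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = (inner ** 3 + rng.random() * (outer ** 3 - inner ** 3)) ** (1.0 / 3.0)
        pos = ligand_coords[k] + d * r
        dm = np.linalg.norm(ligand_coords - pos, axis=1).min()
        if inner < dm <= outer:
            out[got] = pos
            got += 1
    return out


def _water_atoms(n: int, serial_start: int) -> list[Atom]:
    return [
        Atom(serial_start + i, "O", "O", "HOH", i + 1, "W", np.zeros(3))
        for i in range(n)
    ]


def _validate_dwell(dwell_frames: Mapping[str, int]) -> list[str]:
    states = list(dwell_frames)
    order = [s for s in STATE_ORDER if s in states]
    if states != order or any(s not in STATE_ORDER for s in states):
        raise ValueError(
            f"dwell states must follow the ingress order {STATE_ORDER}, got {states}"
        )
    if any(int(dwell_frames[s]) < 1 for s in states):
        raise ValueError("dwell frame counts must be positive")
    return states


def _brute_force_contacts(
    receptor_coords: np.ndarray,
    residue_ids: np.ndarray,
    residue_keys: list[tuple[str, int]],
    ligand_frames: np.ndarray,
    cutoff: float,
) -> dict[tuple[str, int], frozenset[int]]:
    """Per-residue contact frames by direct distance computation (truth pass)."""
    schedule: dict[tuple[str, int], set[int]] = {}
    for f in range(ligand_frames.shape[0]):
        diff = receptor_coords[:, None, :] - ligand_frames[f][None, :, :]
        dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
        hit_atoms = np.nonzero(dmin <= cutoff)[0]
        for rid in np.unique(residue_ids[hit_atoms]):
            schedule.setdefault(residue_keys[rid], set()).add(f)
    return {k: frozenset(v) for k, v in schedule.items()}


# ---------------------------------------------------------------------------
# Translocation trajectories
# ---------------------------------------------------------------------------

def make_translocation_trajectory(
    receptor: Structure,
    ligand_n_atoms: int = 10,
    planted_distances: Mapping[str, float] | None = None,
    dwell_frames: Mapping[str, int] | None = None,
    noise_sd: float = 0.0,
    n_waters: int = 0,
    seed: int = 0,
    solvation_plan: Mapping[str, float] | None = None,
    density: float = BULK_WATER_DENSITY,
    contact_cutoff: float = 4.0,
    shell_cutoff: float = 3.0,
    compute_contact_truth: bool = True,
) -> tuple[Trajectory, TranslocationTruth]:
    """A trajectory whose ligand COM sits at planted distances from the cavity.

    Per frame, the ligand center of mass is placed on the channel axis at
    ``planted_distances[state] + N(0, noise_sd)`` from the cavity center.
    When ``n_waters > 0``, exactly ``round(plan[state] * B)`` waters are
    placed in the ligand's first shell (1.7 < d <= shell_cutoff), where
    ``B`` is the bulk-density-expected shell count; the remaining waters are
    background, kept outside the shell.  The contact schedule in the
    returned truth is recomputed from the emitted coordinates.
    """
    planted = dict(planted_distances or DEFAULT_PLANTED_DISTANCES)
    dwell = dict(dwell_frames or {s: 40 for s in STATE_ORDER})
    states = _validate_dwell(dwell)
    missing = [s for s in states if s not in planted]
    if missing:
        raise ValueError(f"planted_distances missing states: {missing}")
    plan = dict(solvation_plan or DEFAULT_SOLVATION_PLAN)

    rng = np.random.default_rng(seed)
    center = np.asarray(receptor.metadata.get("cavity_center", (0.0, 0.0, 0.0)), float)
    axis = np.asarray(receptor.metadata.get("channel_axis", (0.0, 0.0, 1.0)), float)
    axis = axis / np.linalg.norm(axis)

    schedule = [s for s in states for _ in range(int(dwell[s]))]
    n_frames = len(schedule)
    template = _make_ligand_template(ligand_n_atoms, rng)

    bulk_shell = None
    if n_waters > 0:
        v_shell = _grid_volume(template, 1.7, shell_cutoff)
        bulk_shell = max(3, int(round(density * v_shell)))
        if n_waters < 2 * bulk_shell:
            raise ValueError(
                f"n_waters={n_waters} too small: need at least {2 * bulk_shell} "
                "to cover the planted first shell plus background"
            )

    rec_coords = receptor.coords
    n_rec = receptor.n_atoms
    lig_frames = np.empty((n_frames, ligand_n_atoms, 3))
    wat_frames = (np.empty((n_frames, n_waters, 3)) if n_waters > 0 else None)
    box_half = max(planted.values()) + 10.0

    for f, state in enumerate(schedule):
        d = planted[state]
        if noise_sd > 0:
            d = max(0.0, d + rng.normal(0.0, noise_sd))
        lig = template + center + axis * d
        lig_frames[f] = lig
        if wat_frames is not None:
            n_shell = int(round(plan.get(state, 1.0) * bulk_shell))
            n_shell = min(n_shell, n_waters)
            shell = _sample_shell_waters(lig, n_shell, rng, 1.7, shell_cutoff)
            n_bg = n_waters - n_shell
            bg = np.empty((n_bg, 3))
            got = 0
            while got < n_bg:
                m = 2 * (n_bg - got) + 8
                pts = center + rng.uniform(-box_half, box_half, size=(m, 3))
                dlig = np.sqrt(
                    ((pts[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
                ).min(axis=1)
                pts = pts[dlig > shell_cutoff + 1.0]
                for p in pts:
                    if got < n_bg:
                        bg[got] = p
                        got += 1
            wat_frames[f] = np.vstack([shell, bg]) if n_bg else shell

    atoms = list(receptor.atoms)
    atoms = [
        Atom(a.serial, a.name, a.element, a.res_name, a.res_id, a.chain,
             a.coord, a.charge, a.radius)
        for a in atoms
    ]
    atoms += _ligand_atoms(template, n_rec + 1)
    if n_waters > 0:
        atoms += _water_atoms(n_waters, n_rec + ligand_n_atoms + 1)
    topology = Structure(atoms, metadata=receptor.metadata)

    frames = np.empty((n_frames, topology.n_atoms, 3))
    frames[:, :n_rec, :] = rec_coords[None, :, :]
    frames[:, n_rec:n_rec + ligand_n_atoms, :] = lig_frames
    if wat_frames is not None:
        frames[:, n_rec + ligand_n_atoms:, :] = wat_frames

    contact_schedule: dict[tuple[str, int], frozenset[int]] = {}
    if compute_contact_truth:
        residue_keys = receptor.residue_keys()
        key_to_rid = {k: i for i, k in enumerate(residue_keys)}
        residue_ids = np.array(
            [key_to_rid[a.residue_key] for a in receptor.atoms], dtype=int
        )
        contact_schedule = _brute_force_contacts(
            rec_coords, residue_ids, residue_keys, lig_frames, contact_cutoff
        )

    truth = TranslocationTruth(
        state_schedule=schedule,
        planted_distances={s: planted[s] for s in states},
        contact_schedule=contact_schedule,
        entered_vestibule="vestibule" in states or "binding" in states,
        fully_bound="binding" in states,
        seed=seed,
        bulk_shell_count=bulk_shell,
        solvation_plan=plan if n_waters > 0 else None,
    )
    return Trajectory(topology, frames), truth


def make_contact_schedule_trajectory(
    contact_plan: Mapping[int, int | Sequence[int]],
    n_frames: int,
    seed: int = 0,
    cutoff: float = 4.0,
    n_background: int = 3,
) -> tuple[Trajectory, dict[tuple[str, int], frozenset[int]]]:
    """A toy system planting exact per-residue contact frame sets.

    Each planned residue is a single pseudo-atom that sits at 3.5 A from the
    (fixed, single-atom) ligand during its planted frames and at 9 A
    otherwise; background residues never approach.  ``contact_plan`` maps a
    residue id to either a contact-frame count (frames drawn without
    replacement) or an explicit frame collection.
    """
    rng = np.random.default_rng(seed)
    res_ids = sorted(int(r) for r in contact_plan)
    n_res = len(res_ids) + n_background
    # distinct directions per residue (Fibonacci sphere)
    k = np.arange(n_res)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_res
    rho = np.sqrt(1.0 - z ** 2)
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)

    truth: dict[tuple[str, int], frozenset[int]] = {}
    planted_frames: list[frozenset[int]] = []
    for j, rid in enumerate(res_ids):
        plan = contact_plan[rid]
        if isinstance(plan, (int, np.integer)):
            if not 0 <= int(plan) <= n_frames:
                raise ValueError(f"residue {rid}: contact count {plan} out of range")
            fr = frozenset(
                int(x) for x in rng.choice(n_frames, size=int(plan), replace=False)
            )
        else:
            fr = frozenset(int(x) for x in plan)
            if fr and (min(fr) < 0 or max(fr) >= n_frames):
                raise ValueError(f"residue {rid}: planted frame out of range")
        truth[("A", rid)] = fr
        planted_frames.append(fr)

    atoms = [Atom(1, "C1", "C", "LIG", 1, "L", np.zeros(3))]
    for j, rid in enumerate(res_ids):
        atoms.append(Atom(2 + j, "CA", "C", "RES", rid, "A", dirs[j] * 9.0))
    base = 2 + len(res_ids)
    bg_start = (max(res_ids) if res_ids else 0) + 1
    for b in range(n_background):
        j = len(res_ids) + b
        atoms.append(
            Atom(base + b, "CA", "C", "RES", bg_start + b, "A", dirs[j] * 15.0)
        )
    topology = Structure(atoms)

    frames = np.repeat(topology.coords[None, :, :], n_frames, axis=0)
    for j, fr in enumerate(planted_frames):
        for f in fr:
            frames[f, 1 + j, :] = dirs[j] * 3.5
    return Trajectory(topology, frames), truth


def make_cohort(
    receptor: Structure,
    n_traj: int,
    n_entering: int,
    n_binding: int,
    seed: int = 0,
    frames_per_state: int = 40,
    noise_sd: float = 0.3,
    planted_distances: Mapping[str, float] | None = None,
    compute_contact_truth: bool = False,
) -> tuple[list[Trajectory], CohortTruth]:
    """A cohort with exactly the planted vestibule-entry / full-binding counts.

    The first ``n_binding`` trajectories (before shuffling) run the full
    five-state schedule, the next ``n_entering - n_binding`` stop at the
    vestibule, and the rest stay in bulk/contact.  Dwell lengths are
    jittered by +/-25% around ``frames_per_state``.
    """
    if not (0 <= n_binding <= n_entering <= n_traj):
        raise ValueError("need n_binding <= n_entering <= n_traj, all >= 0")
    planted = dict(planted_distances or DEFAULT_PLANTED_DISTANCES)
    rng = np.random.default_rng(seed)

    kinds = (["binding"] * n_binding
             + ["vestibule"] * (n_entering - n_binding)
             + ["contact"] * (n_traj - n_entering))
    order = rng.permutation(n_traj)

    trajectories: list[Trajectory] = []
    truths: list[TranslocationTruth] = []
    for i in order:
        kind = kinds[i]
        if kind == "binding":
            states = STATE_ORDER
        elif kind == "vestibule":
            states = STATE_ORDER[:4]
        else:
            states = STATE_ORDER[:2]
        dwell = {
            s: max(10, int(round(frames_per_state * rng.uniform(0.75, 1.25))))
            for s in states
        }
        child_seed = int(rng.integers(2 ** 31))
        traj, truth = make_translocation_trajectory(
            receptor,
            planted_distances=planted,
            dwell_frames=dwell,
            noise_sd=noise_sd,
            n_waters=0,
            seed=child_seed,
            compute_contact_truth=compute_contact_truth,
        )
        trajectories.append(traj)
        truths.append(truth)

    cohort = CohortTruth(
        n_trajectories=n_traj,
        n_vestibule_entries=sum(t.entered_vestibule for t in truths),
        n_full_bindings=sum(t.fully_bound for t in truths),
        trajectories=truths,
    )
    assert cohort.n_vestibule_entries == n_entering
    assert cohort.n_full_bindings == n_binding
    return trajectories, cohort


# ---------------------------------------------------------------------------
# Bulk water box
# ---------------------------------------------------------------------------

def make_bulk_water_system(
    ligand: Structure,
    box_edge: float = 24.0,
    density: float = BULK_WATER_DENSITY,
    seed: int = 0,
    n_frames: int = 50,
) -> Trajectory:
    """The ligand alone in a box of uniform single-particle waters.

    Waters are drawn uniformly outside the ligand excluded volume (min
    atom distance > 1.7 A) at the requested number density; each frame is an
    independent draw with the ligand fixed at the box center.  This is the
    bulk reference system for solvation normalization.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    lig_idx = ligand.select("heavy")
    if lig_idx.size == 0:
        raise ValueError("ligand has no heavy atoms")
    lig = ligand.coords[lig_idx] - ligand.coords[lig_idx].mean(axis=0)
    extent = np.abs(lig).max() if lig.size else 0.0
    if extent + 3.0 > box_edge / 2.0:
        raise ValueError(
            f"box_edge={box_edge} too small for ligand extent {extent:.1f} A"
        )
    v_excl = _grid_volume(lig, 0.0, 1.7)
    n_waters = int(round(density * (box_edge ** 3 - v_excl)))
    rng = np.random.default_rng(seed)

    lig_atoms = _ligand_atoms(lig, 1)
    atoms = lig_atoms + _water_atoms(n_waters, len(lig_atoms) + 1)
    topology = Structure(atoms)

    frames = np.empty((n_frames, topology.n_atoms, 3))
    frames[:, : len(lig_atoms), :] = lig[None, :, :]
    half = box_edge / 2.0
    for f in range(n_frames):
        got = 0
        buf = np.empty((n_waters, 3))
        while got < n_waters:
            m = 2 * (n_waters - got) + 8
            pts = rng.uniform(-half, half, size=(m, 3))
            dmin = np.sqrt(
                ((pts[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            pts = pts[dmin > 1.7]
            take = min(len(pts), n_waters - got)
            buf[got:got + take] = pts[:take]
            got += take
        frames[f, len(lig_atoms):, :] = buf
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Alignments with planted identity/similarity
# ---------------------------------------------------------------------------

@dataclass
class ColumnIdentityPlan:
    """Planted pairwise identity/similarity over designated alignment columns.

    ``identity`` and ``similarity`` are fractions in [0, 1] realized exactly
    (constructively) for the designated sequence pair over ``positions``
    (0-based columns).  ``similarity`` defaults to ``identity``.
    """

    positions: Sequence[int]
    identity: float
    similarity: float | None = None

    def __post_init__(self) -> None:
        if self.similarity is None:
            self.similarity = self.identity
        if not (0.0 <= self.identity <= self.similarity <= 1.0):
            raise ValueError("need 0 <= identity <= similarity <= 1")


def _exact_count(fraction: float, n: int, what: str) -> int:
    count = fraction * n
    if abs(count - round(count)) > 1e-9:
        raise ValueError(
            f"infeasible plan: {what}={fraction} is not a multiple of 1/{n}"
        )
    return int(round(count))


def make_alignment(
    n_seqs: int,
    length: int,
    column_identity_plan: ColumnIdentityPlan | None = None,
    seed: int = 0,
    similarity_groups: Sequence[str] | None = None,
) -> Alignment:
    """A gapless random alignment with constructively planted conservation.

    The plan is realized between the first two sequences: over the plan's
    positions, exactly ``identity * n`` columns are identical, exactly
    ``(similarity - identity) * n`` more carry same-group substitutions, and
    the rest carry cross-group substitutions.  Everything else is random.
    """
    if n_seqs < 1 or length < 1:
        raise ValueError("need n_seqs >= 1 and length >= 1")
    groups = list(similarity_groups or DEFAULT_SIMILARITY_GROUPS)
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = [list(rng.choice(aa, size=length)) for _ in range(n_seqs)]

    if column_identity_plan is not None:
        plan = column_identity_plan
        if n_seqs < 2:
            raise ValueError("a pairwise plan needs at least 2 sequences")
        positions = [int(p) for p in plan.positions]
        if any(p < 0 or p >= length for p in positions):
            raise ValueError("plan position out of range")
        if len(set(positions)) != len(positions):
            raise ValueError("plan positions must be unique")
        n_pos = len(positions)
        n_id = _exact_count(plan.identity, n_pos, "identity")
        n_sim = _exact_count(plan.similarity, n_pos, "similarity")
        shuffled = [positions[i] for i in rng.permutation(n_pos)]
        a, b = rows[0], rows[1]
        multi = [g for g in groups if len(g) >= 2]
        for k, p in enumerate(shuffled):
            if k < n_id:
                b[p] = a[p]
            elif k < n_sim:
                g = residue_group(a[p], groups)
                if g is None or len(g) < 2:
                    g = multi[int(rng.integers(len(multi)))]
                    a[p] = g[int(rng.integers(len(g)))]
                others = [x for x in g if x != a[p]]
                b[p] = others[int(rng.integers(len(others)))]
            else:
                ga = residue_group(a[p], groups)
                choices = [
                    x for x in AMINO_ACIDS
                    if residue_group(x, groups) != ga and x != a[p]
                ]
                b[p] = choices[int(rng.integers(len(choices)))]

    sequences = {f"seq{i + 1:04d}": "".join(rows[i]) for i in range(n_seqs)}
    return Alignment(sequences)


# ---------------------------------------------------------------------------
# Complementarity test complexes
# ---------------------------------------------------------------------------

def _ring(center: np.ndarray, radius: float, n: int, axis: int = 0) -> np.ndarray:
    """n points on a circle of given radius around ``center``, normal to ``axis``."""
    theta = 2.0 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    other = [k for k in range(3) if k != axis]
    pts[:, other[0]] = radius * np.cos(theta)
    pts[:, other[1]] = radius * np.sin(theta)
    return pts + center


def make_complementarity_case(
    kind: str, seed: int = 0
) -> tuple[Structure, Structure]:
    """A two-atom ligand in an environment cage with known complementarity sign.

    * ``perfect_electrostatic`` — a +1/-1 ligand dipole, each pole ringed by
      opposite environment charges: surface potentials anticorrelate.
    * ``anti_electrostatic`` — the same cage with conjugated charges.
    * ``hydrophobic_match`` — a hydrophobic (C) / hydrophilic (O) ligand with
      like-facing-like environment rings.
    * ``hydrophobic_clash`` — the rings swapped.
    """
    kinds = {"perfect_electrostatic", "anti_electrostatic",
             "hydrophobic_match", "hydrophobic_clash"}
    if kind not in kinds:
        raise ValueError(f"unknown case kind {kind!r}; choose from {sorted(kinds)}")
    del seed  # cases are fully deterministic; kept for interface uniformity
    p1 = np.array([-3.0, 0.0, 0.0])
    p2 = np.array([+3.0, 0.0, 0.0])
    ring1 = _ring(p1, 4.0, 8, axis=0)
    ring2 = _ring(p2, 4.0, 8, axis=0)

    if kind in {"perfect_electrostatic", "anti_electrostatic"}:
        lig = [
            Atom(1, "C1", "C", "LIG", 1, "L", p1, charge=+1.0, radius=1.7),
            Atom(2, "C2", "C", "LIG", 1, "L", p2, charge=-1.0, radius=1.7),
        ]
        sign = -1.0 if kind == "perfect_electrostatic" else +1.0
        env = []
        for i, p in enumerate(ring1):
            env.append(Atom(i + 1, "C", "C", "CAG", i + 1, "E", p,
                            charge=sign * 0.5, radius=1.7))
        for i, p in enumerate(ring2):
            env.append(Atom(9 + i, "C", "C", "CAG", 9 + i, "E", p,
                            charge=-sign * 0.5, radius=1.7))
    else:
        # small charges (below the charged-polar threshold) ride along so the
        # matched pose also wins on the electrostatic metric in pose ranking
        lig = [
            Atom(1, "C1", "C", "LIG", 1, "L", p1, charge=+0.25, radius=1.7),
            Atom(2, "O1", "O", "LIG", 1, "L", p2, charge=-0.25, radius=1.52),
        ]
        swap = kind == "hydrophobic_clash"
        elem1, elem2 = ("O", "C") if swap else ("C", "O")
        q1, q2 = (+0.25, -0.25) if swap else (-0.25, +0.25)
        env = []
        for i, p in enumerate(ring1):
            env.append(Atom(i + 1, elem1, elem1, "CAG", i + 1, "E", p,
                            charge=q1, radius=1.7))
        for i, p in enumerate(ring2):
            env.append(Atom(9 + i, elem2, elem2, "CAG", 9 + i, "E", p,
                            charge=q2, radius=1.7))
    return Structure(lig), Structure(env)
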