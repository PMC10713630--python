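"""Orchestration of the analysis stages into reproducible runs.

Every output file starts with a header line recording the package version,
a hash of the run configuration, and the seed, so a run can be replayed
byte-for-byte.  Plots are secondary artifacts; all downstream consumers
depend only on the TSV/JSON tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .contacts import cohort_frequencies, contact_frequencies
from .geometry import SitePoint
from .io import write_alignment, write_structure, write_trajectory
from .pockets import (KYTE_DOOLITTLE_POLARITY, compare_homolog_pockets)
from .solvation import bulk_reference, solvation_fraction
from .structure import Structure, Trajectory
from .synthetic import (make_alignment, make_bulk_water_system, make_cohort,
                        make_toy_receptor, make_translocation_trajectory,
                        ColumnIdentityPlan)
from .translocation import (StateThresholds, detect_entry_events,
                            distance_series, segment_states,
                            select_representative_frames, summarize_cohort)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_synth", "run_ingress", "run_pockets", "run_conserve"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are complete.

    Selections use the package selection-string language; cutoffs in A.
    """

    ligand_selection: str = "chain L"
    receptor_selection: str = "chain A"
    water_selection: str = "water"
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    contact_cutoff: float = 4.0
    solvation_cutoff: float = 3.0
    lining_cutoff: float = 4.5
    kmeans_k: int = 4
    seed: int = 0
    segmentation_method: str = "changepoint"
    contact_window: str = "after_first_contact"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (f"# ligandpath v{__version__} config={self.config_hash()} "
                f"seed={self.seed}")


def _write_tsv(path: str, header: str, columns: Sequence[str],
               rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_json(path: str, header_info: dict, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"_meta": header_info, **payload}, fh, indent=1)


def run_synth(
    out_dir: str,
    config: RunConfig | None = None,
    n_traj: int = 8,
    n_entering: int = 3,
    n_binding: int = 1,
    n_receptor_residues: int = 900,
) -> dict:
    """Generate a full synthetic dataset (receptor, cohort, solvated
    trajectory, bulk box, alignment) with a truth JSON sidecar."""
    cfg = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    receptor = make_toy_receptor(n_receptor_residues, seed=cfg.seed)
    write_structure(os.path.join(out_dir, "receptor.pdb"), receptor)

    trajectories, cohort_truth = make_cohort(
        receptor, n_traj, n_entering, n_binding, seed=cfg.seed)
    for i, traj in enumerate(trajectories):
        write_trajectory(os.path.join(out_dir, f"traj_{i:03d}.pdb"), traj)

    solv_traj, solv_truth = make_translocation_trajectory(
        receptor, n_waters=80, seed=cfg.seed + 1)
    write_trajectory(os.path.join(out_dir, "traj_solvated.pdb"), solv_traj)

    aln = make_alignment(
        20, 120, ColumnIdentityPlan(list(range(100)), 0.73, 0.82),
        seed=cfg.seed)
    write_alignment(os.path.join(out_dir, "orco_family.fasta"), aln)

    meta = {"version": __version__, "config": cfg.config_hash(), "seed": cfg.seed}
    _write_json(os.path.join(out_dir, "truth.json"), meta, {
        "cohort": cohort_truth.to_dict(),
        "solvated_trajectory": solv_truth.to_dict(),
        "receptor": receptor.metadata,
    })
    logger.info("synthetic dataset written to %s", out_dir)
    return {"out_dir": out_dir, "n_traj": n_traj}


def run_ingress(
    out_dir: str,
    trajectories: Sequence[Trajectory],
    site: SitePoint,
    config: RunConfig | None = None,
    make_plot: bool = True,
) -> dict:
    """The end-to-end ingress analysis over one or more trajectories.

    Emits per-trajectory distance/segmentation tables, entry events, contact
    frequencies, solvation series (skipped with a warning when a trajectory
    carries no waters), representative frames, a cohort summary, and a
    combined distance/solvation figure for the first trajectory.
    """
    cfg = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    header = cfg.header()
    events = []
    tables = []
    first_series = None
    first_solv = None
    for i, traj in enumerate(trajectories):
        series = distance_series(traj, cfg.ligand_selection,
                                 cfg.receptor_selection, site)
        seg = segment_states(series, method=cfg.segmentation_method,
                             thresholds=cfg.thresholds)
        ev = detect_entry_events(series, cfg.thresholds)
        events.append(ev)
        _write_tsv(
            os.path.join(out_dir, f"distance_{i:03d}.tsv"), header,
            ["frame", "distance_A", "state"],
            [(f, f"{series.distances[f]:.4f}", seg.labels[f])
             for f in range(len(series))],
        )
        try:
            table = contact_frequencies(
                traj, cfg.ligand_selection, cfg.contact_cutoff,
                cfg.contact_window, receptor_selection=cfg.receptor_selection)
            rows = [(c, r, n, f"{table.frequency(c, r):.4f}")
                    for c, r, n in table.residues]
            tables.append(table)
        except ValueError:
            logger.warning("trajectory %d: no receptor contact; "
                           "empty contact table", i)
            rows = []
        _write_tsv(
            os.path.join(out_dir, f"contacts_{i:03d}.tsv"), header,
            ["chain", "res_id", "res_name", "frequency"], rows,
        )
        water_idx = traj.topology.select(cfg.water_selection)
        if water_idx.size:
            bulk_frames = [f for f, lab in enumerate(seg.labels) if lab == "bulk"]
            if len(bulk_frames) >= 5:
                bulk = bulk_reference(traj, cfg.ligand_selection,
                                      cfg.water_selection, cfg.solvation_cutoff,
                                      frames=np.array(bulk_frames))
                solv = solvation_fraction(traj, cfg.ligand_selection,
                                          cfg.water_selection, bulk,
                                          cfg.solvation_cutoff)
                _write_tsv(
                    os.path.join(out_dir, f"solvation_{i:03d}.tsv"), header,
                    ["frame", "count", "fraction"],
                    [(f, solv.shell_counts[f], f"{solv.fraction[f]:.4f}")
                     for f in range(len(solv.fraction))],
                )
                if first_solv is None:
                    first_solv = solv
            else:
                logger.warning("trajectory %d: too few bulk frames for "
                               "solvation normalization; stage skipped", i)
        else:
            logger.warning("trajectory %d: no waters; solvation skipped", i)
        reps = select_representative_frames(
            traj, seg, cfg.ligand_selection, k=cfg.kmeans_k, seed=cfg.seed)
        for state, frame_i in reps.items():
            write_structure(
                os.path.join(out_dir, f"rep_{i:03d}_{state}.pdb"),
                traj.frame_structure(frame_i),
            )
        if first_series is None:
            first_series = series

    summary = summarize_cohort(events)
    meta = {"version": __version__, "config": cfg.config_hash(), "seed": cfg.seed}
    _write_json(os.path.join(out_dir, "cohort_summary.json"), meta, {
        "n_trajectories": summary[0],
        "n_vestibule_entries": summary[1],
        "n_full_bindings": summary[2],
    })
    if make_plot and first_series is not None:
        _plot_ingress(os.path.join(out_dir, "ingress.png"),
                      first_series, first_solv)
    return {"summary": summary, "out_dir": out_dir}


def _plot_ingress(path, series, solv) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(series.frame_indices, series.distances, lw=1.2, color="tab:green")
    ax.set_xlabel("frame")
    ax.set_ylabel("ligand COM to site distance (A)")
    if solv is not None:
        ax2 = ax.twinx()
        ax2.fill_between(np.arange(len(solv.fraction)),
                         100.0 * solv.fraction, alpha=0.25, color="tab:blue")
        ax2.set_ylabel("solvation (% of bulk)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pockets(
    out_dir: str,
    models: Sequence[tuple[str, Structure]],
    config: RunConfig | None = None,
    guide_point=None,
    scale=KYTE_DOOLITTLE_POLARITY,
) -> dict:
    """Comparative pocket detection/polarity over homolog models."""
    cfg = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    selector = "nearest_to_point" if guide_point is not None else "largest"
    table = compare_homolog_pockets(models, selector, scale,
                                    guide_point=guide_point,
                                    lining_cutoff=cfg.lining_cutoff)
    rows = [
        (r["name"],
         f"{r['volume']:.1f}" if np.isfinite(r["volume"]) else "NA",
         f"{r['polarity']:.3f}" if np.isfinite(r["polarity"]) else "NA",
         r["n_lining"])
        for _, r in table.iterrows()
    ]
    _write_tsv(os.path.join(out_dir, "pockets.tsv"), cfg.header(),
               ["name", "volume_A3", "polarity", "n_lining"], rows)
    return {"table": table, "out_dir": out_dir}


def run_conserve(
    out_dir: str,
    alignment,
    positions: Sequence[int],
    pair: tuple[str, str],
    config: RunConfig | None = None,
) -> dict:
    """Pocket conservation percentages plus a bits logo matrix."""
    from .conservation import logo_matrix, pocket_identity

    cfg = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    cons = pocket_identity(alignment, pair[0], pair[1], positions)
    logo = logo_matrix(alignment, positions, units="bits")
    meta = {"version": __version__, "config": cfg.config_hash(), "seed": cfg.seed}
    _write_json(os.path.join(out_dir, "conservation.json"), meta, {
        "pair": list(cons.pair),
        "identity_pct": cons.identity_pct,
        "similarity_pct": cons.similarity_pct,
        "n_compared": cons.n_compared,
    })
    logo_path = os.path.join(out_dir, "logo_bits.tsv")
    with open(logo_path, "w") as fh:
        fh.write(cfg.header() + "\n")
        logo.to_csv(fh, sep="\t")
    return {"conservation": cons, "out_dir": out_dir}
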