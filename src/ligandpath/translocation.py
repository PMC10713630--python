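"""The core ingress analysis: per-frame site distance, four-state
segmentation, entry/binding event detection, cohort tallies, and
representative-frame selection.

A translocation event is read off the distance between the ligand center of
mass and a fixed binding-site point (mapped from a reference complex).  The
curve is segmented into the four metastable steps of ingress — contact,
entry, vestibule, binding — either by distance thresholds with a dwell
filter or by least-squares changepoint fitting; events are counted from
dwell-filtered threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import SitePoint, center_of_mass, kabsch_superpose
from .structure import Structure, Trajectory

__all__ = [
    "DistanceSeries",
    "StateSegmentation",
    "EntryEvents",
    "StateThresholds",
    "distance_series",
    "segment_states",
    "detect_entry_events",
    "summarize_cohort",
    "select_representative_frames",
]

#: State labels in ingress order (bulk is only used by the threshold method).
INGRESS_STATES = ("bulk", "contact", "entry", "vestibule", "binding")


@dataclass
class StateThresholds:
    """Distance criteria (A) separating the ingress states, with a dwell filter.

    A frame is labeled by the innermost threshold its distance undercuts;
    ``min_dwell`` consecutive frames are required before a state change (or
    an entry/binding event) is committed.  The defaults are calibrated on
    the synthetic receptor family; real systems should set their own.
    """

    d_contact: float = 25.0
    d_entry: float = 15.0
    d_vestibule: float = 9.0
    d_binding: float = 4.0
    min_dwell: int = 5

    def __post_init__(self) -> None:
        if not (self.d_contact > self.d_entry > self.d_vestibule
                > self.d_binding > 0):
            raise ValueError("need d_contact > d_entry > d_vestibule > d_binding > 0")
        if self.min_dwell < 1:
            raise ValueError("min_dwell must be >= 1")

    def label(self, d: float) -> str:
        if d < self.d_binding:
            return "binding"
        if d < self.d_vestibule:
            return "vestibule"
        if d < self.d_entry:
            return "entry"
        if d < self.d_contact:
            return "contact"
        return "bulk"


@dataclass
class DistanceSeries:
    """Per-frame ligand-COM-to-site distances (A)."""

    distances: np.ndarray
    frame_indices: np.ndarray
    site: SitePoint
    ligand_selection: object = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.distances.shape != self.frame_indices.shape:
            raise ValueError("distances and frame_indices must match in length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.distances.size


@dataclass
class StateSegmentation:
    """Piecewise-constant state labels over a distance series."""

    labels: list[str]
    boundaries: list[int]   # first frame index of each segment after the first
    method: str

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")

    def segments(self) -> list[tuple[int, int, str]]:
        """(start, stop, label) triples; stop is exclusive."""
        n = len(self.labels)
        starts = [0] + list(self.boundaries)
        stops = list(self.boundaries) + [n]
        return [(a, b, self.labels[a]) for a, b in zip(starts, stops)]

    def frames_in_state(self, state: str) -> np.ndarray:
        return np.nonzero(np.array(self.labels) == state)[0]


@dataclass
class EntryEvents:
    """Vestibule-entry and full-binding flags for one trajectory."""

    entered_vestibule: bool
    fully_bound: bool
    first_vestibule_frame: int | None = None
    first_binding_frame: int | None = None

    def __post_init__(self) -> None:
        if self.fully_bound and not self.entered_vestibule:
            raise ValueError("fully_bound implies entered_vestibule")


def distance_series(
    trajectory: Trajectory,
    ligand_selection,
    receptor_selection,
    site: SitePoint,
    align_each_frame: bool = False,
    weighting: str = "mass",
) -> DistanceSeries:
    """Ligand-COM distance to the site point, frame by frame.

    With ``align_each_frame`` the receptor selection of every frame is
    superposed onto the first frame before measuring, so a site point
    expressed in the first frame's coordinates stays valid even if the whole
    system drifts or rotates.
    """
    top = trajectory.topology
    lig_idx = top.select(ligand_selection)
    rec_idx = top.select(receptor_selection)
    if lig_idx.size == 0 or rec_idx.size == 0:
        raise ValueError("ligand and receptor selections must be non-empty")
    site_coord = site.coord
    n = trajectory.n_frames
    out = np.empty(n)
    ref = trajectory.frames[0][rec_idx]
    for f in range(n):
        frame = trajectory.frames[f]
        if align_each_frame and f > 0:
            sup = kabsch_superpose(frame[rec_idx], ref)
            frame = sup.apply(frame)
        com = center_of_mass(top, lig_idx, weighting=weighting, frame=frame)
        out[f] = np.linalg.norm(com - site_coord)
    return DistanceSeries(
        distances=out,
        frame_indices=np.arange(n),
        site=site,
        ligand_selection=ligand_selection,
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _merge_short_runs(labels: list[str], min_dwell: int) -> list[str]:
    """Absorb runs shorter than min_dwell into the preceding run."""
    out = list(labels)
    changed = True
    while changed:
        changed = False
        runs: list[tuple[int, int, str]] = []
        start = 0
        for i in range(1, len(out) + 1):
            if i == len(out) or out[i] != out[start]:
                runs.append((start, i, out[start]))
                start = i
        for k, (a, b, lab) in enumerate(runs):
            if b - a < min_dwell and k > 0:
                out[a:b] = [runs[k - 1][2]] * (b - a)
                changed = True
                break
    return out


def _binary_segmentation(x: np.ndarray, n_breaks: int) -> list[int]:
    """Breakpoints of a least-squares piecewise-constant fit (binary splits)."""

    def sse(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum()) if hi > lo else 0.0

    def best_split(lo: int, hi: int) -> tuple[float, int] | None:
        if hi - lo < 2:
            return None
        base = sse(lo, hi)
        seg = x[lo:hi]
        csum = np.cumsum(seg)
        csq = np.cumsum(seg ** 2)
        n = hi - lo
        best: tuple[float, int] | None = None
        for k in range(1, n):
            left = csq[k - 1] - csum[k - 1] ** 2 / k
            right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
            gain = base - (left + right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, lo + k)
        return best

    segments: list[tuple[int, int]] = [(0, len(x))]
    breaks: list[int] = []
    for _ in range(n_breaks):
        candidates = []
        for lo, hi in segments:
            s = best_split(lo, hi)
            if s is not None:
                candidates.append((s[0], s[1], lo, hi))
        if not candidates:
            break
        _, split, lo, hi = max(candidates, key=lambda c: c[0])
        segments.remove((lo, hi))
        segments += [(lo, split), (split, hi)]
        breaks.append(split)
    return sorted(breaks)


def segment_states(
    series: DistanceSeries,
    method: str = "changepoint",
    n_states: int = 4,
    thresholds: StateThresholds | None = None,
) -> StateSegmentation:
    """Segment a distance series into the metastable ingress states.

    ``threshold``: label every frame by the thresholds, then absorb runs
    shorter than ``min_dwell`` into their predecessor (hysteresis).

    ``changepoint``: fit a piecewise-constant mean with ``n_states - 1``
    breakpoints by least-squares binary segmentation and name the segments
    by their mean-distance rank, outermost first.  This is the method for
    reproducing the visual division of a prototypical binding trajectory;
    threshold labeling is preferred for event counting.
    """
    thr = thresholds or StateThresholds()
    x = series.distances
    if method == "threshold":
        raw = [thr.label(d) for d in x]
        labels = _merge_short_runs(raw, thr.min_dwell)
    elif method == "changepoint":
        if len(x) < n_states * thr.min_dwell:
            raise ValueError(
                f"series of length {len(x)} too short for {n_states} states"
            )
        breaks = _binary_segmentation(x, n_states - 1)
        bounds = [0] + breaks + [len(x)]
        seg_means = [x[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        # outermost (largest mean distance) first among the ingress states
        state_names = list(INGRESS_STATES[-len(seg_means):]) if len(seg_means) <= 5 \
            else [f"state{i}" for i in range(len(seg_means))]
        order = np.argsort(seg_means)[::-1]
        seg_labels = [""] * len(seg_means)
        for rank, seg_i in enumerate(order):
            seg_labels[seg_i] = state_names[rank]
        labels = []
        for (a, b), lab in zip(zip(bounds, bounds[1:]), seg_labels):
            labels += [lab] * (b - a)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    boundaries = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
    return StateSegmentation(labels=labels, boundaries=boundaries, method=method)


def _first_dwell_frame(below: np.ndarray, min_dwell: int) -> int | None:
    """First index of a run of >= min_dwell consecutive True values."""
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= min_dwell:
            return i - min_dwell + 1
    return None


def detect_entry_events(
    series: DistanceSeries,
    thresholds: StateThresholds | None = None,
) -> EntryEvents:
    """Vestibule-entry / full-binding events with a consecutive-dwell filter.

    The ligand has entered the vestibule (resp. bound) iff its site distance
    stays below ``d_vestibule`` (resp. ``d_binding``) for at least
    ``min_dwell`` consecutive frames.
    """
    thr = thresholds or StateThresholds()
    x = series.distances
    v = _first_dwell_frame(x < thr.d_vestibule, thr.min_dwell)
    b = _first_dwell_frame(x < thr.d_binding, thr.min_dwell)
    return EntryEvents(
        entered_vestibule=v is not None,
        fully_bound=b is not None,
        first_vestibule_frame=v,
        first_binding_frame=b,
    )


def summarize_cohort(events: Sequence[EntryEvents]) -> tuple[int, int, int]:
    """(n_trajectories, n_vestibule_entries, n_full_bindings)."""
    n = len(events)
    n_vest = sum(e.entered_vestibule for e in events)
    n_full = sum(e.fully_bound for e in events)
    return (n, n_vest, n_full)


# ---------------------------------------------------------------------------
# Representative frames
# ---------------------------------------------------------------------------

def _contact_fingerprints(
    trajectory: Trajectory, ligand_idx: np.ndarray, cutoff: float = 4.0
) -> np.ndarray:
    from .contacts import frame_contacts  # local import to avoid a cycle

    top = trajectory.topology
    keys = top.residue_keys()
    key_pos = {k: i for i, k in enumerate(keys)}
    fp = np.zeros((trajectory.n_frames, len(keys)))
    for f in range(trajectory.n_frames):
        for key in frame_contacts(top, trajectory.frames[f], ligand_idx, cutoff):
            fp[f, key_pos[key]] = 1.0
    return fp


def select_representative_frames(
    trajectory: Trajectory,
    segmentation: StateSegmentation,
    ligand_selection,
    feature: str = "ligand_coords",
    k: int = 4,
    seed: int = 0,
) -> dict[str, int]:
    """Per-state representative frame via k-means on a per-frame feature.

    Within each state's frames, k-means (k-means++ init, 10 restarts, fixed
    seed) clusters either the flattened ligand coordinates or the
    ligand-residue contact fingerprint; the representative is the frame
    nearest the centroid of the most populated cluster (medoid rule), ties
    broken toward the lowest frame index.  States with fewer than ``k``
    frames get k reduced; empty states are skipped.
    """
    from sklearn.cluster import KMeans

    if feature not in {"ligand_coords", "contact_fingerprint"}:
        raise ValueError(f"unknown feature {feature!r}")
    top = trajectory.topology
    lig_idx = top.select(ligand_selection)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    if feature == "ligand_coords":
        feats = trajectory.frames[:, lig_idx, :].reshape(trajectory.n_frames, -1)
    else:
        feats = _contact_fingerprints(trajectory, lig_idx)

    reps: dict[str, int] = {}
    for state in dict.fromkeys(segmentation.labels):
        frames = segmentation.frames_in_state(state)
        if frames.size == 0:
            continue
        kk = min(k, frames.size)
        X = feats[frames]
        km = KMeans(n_clusters=kk, init="k-means++", n_init=10, random_state=seed)
        assign = km.fit_predict(X)
        sizes = np.bincount(assign, minlength=kk)
        largest = int(np.argmax(sizes))  # argmax takes the lowest index on ties
        members = np.nonzero(assign == largest)[0]
        dists = np.linalg.norm(X[members] - km.cluster_centers_[largest], axis=1)
        best = members[np.lexsort((frames[members], np.round(dists, 10)))[0]]
        reps[state] = int(frames[best])
    return reps
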