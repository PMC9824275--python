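"""Contact analytics between a nanoparticle and an annotated fibril.

A fibril residue is *in contact* when the minimum-image, centre-to-
centre distance between any of its beads and any nanoparticle bead is
at or below the cutoff (default 0.8 nm; the boundary is closed).
"Number of contacts" therefore counts residues, not bead pairs.

The module provides per-frame contact records, class-resolved time
series, persistence-filtered first-contact times, per-position contact
frequencies and the side/frontal contact-type call used to summarise a
whole trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    AnnotationError,
    ConfigurationError,
    InputConsistencyError,
    InvalidArgumentError,
)
from .fibril_builder import FibrilModel
from .synthetic_data import Trajectory

logger = logging.getLogger("nanofib")

DEFAULT_CUTOFF_NM = 0.8
CLASSES = ("hydrophobic", "polar", "charged")


@dataclass(frozen=True)
class ContactRecord:
    """One contacting residue in one frame."""

    frame: int
    chain: int
    residue_index: int      # 1-based sequence position
    distance: float         # nm, min bead-bead distance
    res_class: str
    face: str               # 'frontal' | 'side' | ''


def contacts_in_frame(
    coords: np.ndarray,
    np_index: np.ndarray,
    fibril: FibrilModel,
    cutoff: float = DEFAULT_CUTOFF_NM,
    box: np.ndarray | None = None,
    frame: int = 0,
    fibril_index: np.ndarray | None = None,
) -> list[ContactRecord]:
    """Contacting residues in one frame (KD-tree accelerated, PBC aware).

    *coords* holds the full system; *np_index* selects NP beads and
    *fibril_index* (default: all remaining beads, in fibril residue
    order) the fibril beads, one per residue.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be > 0")
    coords = np.asarray(coords)
    np_index = np.asarray(np_index, dtype=np.int64)
    if fibril_index is None:
        mask = np.ones(len(coords), dtype=bool)
        mask[np_index] = False
        fibril_index = np.nonzero(mask)[0]
    fibril_index = np.asarray(fibril_index, dtype=np.int64)
    if len(fibril_index) != fibril.n_residues:
        raise InputConsistencyError(
            f"component index selects {len(fibril_index)} fibril beads but the "
            f"fibril has {fibril.n_residues} residues"
        )
    if len(np_index) == 0:
        return []
    fib = coords[fibril_index]
    npb = coords[np_index]
    if box is not None:
        box = np.asarray(box, dtype=float)
        # nearest NP bead per fibril residue, minimum-image
        dres, _ = cKDTree(np.mod(npb, box), boxsize=box).query(np.mod(fib, box), k=1)
    else:
        dres, _ = cKDTree(npb).query(fib, k=1)
    hit = np.nonzero(dres <= cutoff)[0]
    classes = fibril.classes
    faces = fibril.face_labels
    return [
        ContactRecord(
            frame=frame,
            chain=int(fibril.chain_of_residue[j]),
            residue_index=int(fibril.residue_index[j]),
            distance=float(dres[j]),
            res_class=str(classes[j]),
            face="" if faces is None else str(faces[j]),
        )
        for j in hit
    ]


def trajectory_contacts(
    traj: Trajectory,
    fibril: FibrilModel,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> list[list[ContactRecord]]:
    """Contact records for every frame of a trajectory."""
    return [
        contacts_in_frame(
            traj.frames[k], traj.np_index, fibril, cutoff=cutoff,
            box=traj.box, frame=k, fibril_index=traj.fibril_index,
        )
        for k in range(traj.n_frames)
    ]


def class_breakdown(records: list[ContactRecord]) -> dict[str, int]:
    """Count records by residue class; the counts partition the set."""
    counts = {c: 0 for c in CLASSES}
    for r in records:
        if r.res_class not in counts:
            raise AnnotationError(f"record with unknown class {r.res_class!r}")
        counts[r.res_class] += 1
    return counts


def contact_timeseries(
    traj: Trajectory,
    fibril: FibrilModel,
    cutoff: float = DEFAULT_CUTOFF_NM,
    records: list[list[ContactRecord]] | None = None,
) -> pd.DataFrame:
    """Per-frame contact counts, total and by residue class."""
    if records is None:
        records = trajectory_contacts(traj, fibril, cutoff)
    rows = []
    for k, recs in enumerate(records):
        counts = class_breakdown(recs)
        rows.append({
            "frame": k,
            "time": float(traj.times[k]),
            "total": len(recs),
            **counts,
        })
    return pd.DataFrame(rows, columns=["frame", "time", "total", *CLASSES])


def first_contact_time(
    series: pd.DataFrame | np.ndarray,
    persistence: int = 1,
    times: np.ndarray | None = None,
) -> float | None:
    """Time of the first frame opening a run of >= *persistence* contact frames.

    *series* is the per-frame total contact count (or the DataFrame from
    :func:`contact_timeseries`). Returns ``None`` when no qualifying run
    exists.
    """
    if persistence < 1:
        raise InvalidArgumentError("persistence must be >= 1")
    if isinstance(series, pd.DataFrame):
        if times is None:
            times = series["time"].to_numpy()
        series = series["total"].to_numpy()
    series = np.asarray(series)
    if series.size == 0:
        raise InvalidArgumentError("empty contact series")
    if times is None:
        times = np.arange(len(series), dtype=float)
    has = series > 0
    run = 0
    for k, h in enumerate(has):
        run = run + 1 if h else 0
        if run >= persistence:
            return float(times[k - persistence + 1])
    return None


def residue_contact_frequency(
    traj: Trajectory,
    fibril: FibrilModel,
    cutoff: float = DEFAULT_CUTOFF_NM,
    aggregate: str = "position",
    records: list[list[ContactRecord]] | None = None,
) -> pd.Series:
    """Fraction of frames each residue spends in contact.

    ``aggregate="position"`` reports one frequency per sequence position
    (a position counts as contacting in a frame when any chain's copy
    is), mirroring per-position involvement profiles;
    ``aggregate="chain"`` reports one per (chain, position) pair.
    """
    if records is None:
        records = trajectory_contacts(traj, fibril, cutoff)
    n_frames = traj.n_frames
    if aggregate == "position":
        positions = np.unique(fibril.residue_index)
        hits = {int(p): 0 for p in positions}
        for recs in records:
            for p in {r.residue_index for r in recs}:
                hits[p] += 1
        return pd.Series(
            {p: hits[p] / n_frames for p in hits}, name="frequency"
        ).sort_index()
    elif aggregate == "chain":
        keys = {(int(c), int(p)) for c, p in
                zip(fibril.chain_of_residue, fibril.residue_index)}
        hits = {k: 0 for k in keys}
        for recs in records:
            for k in {(r.chain, r.residue_index) for r in recs}:
                hits[k] += 1
        idx = pd.MultiIndex.from_tuples(sorted(hits), names=["chain", "position"])
        return pd.Series([hits[k] / n_frames for k in sorted(hits)], index=idx,
                         name="frequency")
    raise InvalidArgumentError(f"unknown aggregate mode {aggregate!r}")


def classify_contact_type(
    records: list[list[ContactRecord]] | list[ContactRecord],
    threshold: float = 0.5,
    persistence: int = 1,
) -> str:
    """Side/frontal call for a trajectory: event-weighted majority.

    Counts contact events (residue-frames) on frontal-face residues
    among all events from the first persistent contact onward; returns
    ``"frontal"`` when their fraction exceeds *threshold*, ``"side"``
    otherwise (ties break to side, the modal outcome), and ``"none"``
    when no contact ever forms.
    """
    if records and isinstance(records[0], ContactRecord):
        per_frame = [list(records)]
    else:
        per_frame = [list(f) for f in records]
    totals = np.array([len(f) for f in per_frame])
    if totals.sum() == 0:
        return "none"
    start = first_contact_time(totals, persistence=persistence)
    events = [
        r for k, frame in enumerate(per_frame) if start is None or k >= start
        for r in frame
    ]
    if not events:
        return "none"
    if any(r.face == "" for r in events):
        raise ConfigurationError(
            "face masks undefined; run define_faces on the fibril first"
        )
    frontal = sum(1 for r in events if r.face == "frontal")
    return "frontal" if frontal / len(events) > threshold else "side"


@dataclass
class ContactSummary:
    """Everything the contact pipeline reports for one trajectory."""

    per_frame: pd.DataFrame
    residue_frequency: pd.Series
    first_contact: float | None
    contact_type: str
    class_totals: dict[str, int]
    cutoff: float
    persistence: int
    species: str = ""
    replica: int = 0


def analyze_trajectory(
    traj: Trajectory,
    fibril: FibrilModel,
    cutoff: float = DEFAULT_CUTOFF_NM,
    persistence: int = 1,
    threshold: float = 0.5,
) -> ContactSummary:
    """Run the full contact pipeline on one trajectory."""
    records = trajectory_contacts(traj, fibril, cutoff)
    ts = contact_timeseries(traj, fibril, cutoff, records=records)
    totals = {c: int(ts[c].sum()) for c in CLASSES}
    summary = ContactSummary(
        per_frame=ts,
        residue_frequency=residue_contact_frequency(
            traj, fibril, cutoff, records=records
        ),
        first_contact=first_contact_time(ts, persistence=persistence),
        contact_type=classify_contact_type(records, threshold=threshold,
                                           persistence=persistence),
        class_totals=totals,
        cutoff=cutoff,
        persistence=persistence,
        species=traj.species,
        replica=traj.replica,
    )
    logger.info(
        "analyze_trajectory: species=%s replica=%d type=%s first_contact=%s",
        summary.species, summary.replica, summary.contact_type,
        summary.first_contact,
    )
    return summary
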