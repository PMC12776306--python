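"""Binding-event detection and residence-lifetime statistics.

A lipid headgroup is *bound* to a residue in a frame when the minimum
distance between the lipid atom group and the residue's sidechain heavy
atoms is <= ``cutoff_A`` (default 5 Å, boundary inclusive).  Maximal runs
of bound frames form events; two runs separated by a gap of *strictly
fewer* than ``merge_gap_frames`` unbound frames (default 10) are merged
into one event spanning the gap, so brief sub-threshold excursions
("flickers") do not fragment a residence.  Events touching the first or
last frame are flagged censored: their true duration is unknown.

Per residue, statistics aggregate events over all lipid copies (and,
in a symmetric multimer, over subunits mapped to one residue label):
event count N, arithmetic-mean duration and longest duration, the
columns of a residence-lifetime table.  A 1-frame event has duration
``frame_interval_ns`` (inclusive frame count times dt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtomGroup, Trajectory, min_image_distance_matrix

__all__ = [
    "DistanceSeries",
    "EventConfig",
    "BindingEvent",
    "ResidenceStats",
    "compute_distance_series",
    "detect_events",
    "residence_stats",
    "export_events",
    "STATS_COLUMNS",
]

#: residence-table column order: residue, state, N, mean, longest
STATS_COLUMNS = [
    "residue",
    "state",
    "total_events",
    "mean_duration_ns",
    "longest_event_ns",
]


@dataclass
class DistanceSeries:
    """Per-frame minimum lipid-to-residue distance for one pair."""

    lipid_id: str
    residue_key: tuple[str, int]
    distances_A: np.ndarray
    frame_interval_ns: float

    def __post_init__(self) -> None:
        self.distances_A = np.asarray(self.distances_A, dtype=np.float64)
        if self.distances_A.ndim != 1:
            raise ValueError("distances_A must be 1-D")
        if np.any(self.distances_A < 0):
            raise ValueError("distances must be non-negative")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")


@dataclass(frozen=True)
class EventConfig:
    """Detection parameters.

    cutoff_A: bound threshold, boundary inclusive.
    merge_gap_frames: gaps of strictly fewer unbound frames are merged;
        a gap of exactly this many frames splits events.  0 disables
        merging.
    min_event_frames: events shorter than this (after merging) are
        dropped.
    """

    cutoff_A: float = 5.0
    merge_gap_frames: int = 10
    min_event_frames: int = 1

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be positive")
        if self.merge_gap_frames < 0 or self.min_event_frames < 0:
            raise ValueError("frame counts must be non-negative")


@dataclass(frozen=True)
class BindingEvent:
    lipid_id: str
    residue_key: tuple[str, int]
    start_frame: int
    end_frame: int  # inclusive
    duration_ns: float
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ResidenceStats:
    residue_key: tuple[str, int]
    state_label: str
    n_events: int
    mean_duration_ns: float | None
    longest_duration_ns: float | None


def compute_distance_series(
    traj: Trajectory,
    lipid_atom_groups: dict[str, AtomGroup],
    residue_groups: dict[tuple[str, int], AtomGroup],
) -> list[DistanceSeries]:
    """Per (lipid, residue) pair, the per-frame minimum minimum-image
    distance over all (lipid atom, residue atom) pairs.

    Residues with empty atom groups (e.g. a glycine under a sidechain
    selection) are skipped with a warning.
    """
    residue_groups = dict(residue_groups)
    for key, grp in list(residue_groups.items()):
        if len(grp) == 0:
            warnings.warn(f"residue {key} has an empty atom group; skipped",
                          stacklevel=2)
            del residue_groups[key]
    for lid, grp in lipid_atom_groups.items():
        if len(grp) == 0:
            raise ValueError(f"lipid group {lid!r} is empty")
    coords = traj.coordinates()  # (n_frames, n_atoms, 3)
    box_list = [fr.box for fr in traj.frames]
    if all(b is None for b in box_list):
        boxes = None
    elif any(b is None for b in box_list):
        raise ValueError("mixed periodic/non-periodic frames are not supported")
    else:
        boxes = np.stack(box_list)[:, None, None, :]  # broadcast over pairs
    out = []
    for lid, lgrp in lipid_atom_groups.items():
        for rkey, rgrp in residue_groups.items():
            delta = (
                coords[:, lgrp.atom_ids, None, :]
                - coords[:, None, rgrp.atom_ids, :]
            )
            if boxes is not None:
                delta = delta - boxes * np.round(delta / boxes)
            dist = np.sqrt(np.einsum("fijk,fijk->fij", delta, delta)).min(axis=(1, 2))
            out.append(DistanceSeries(lid, rkey, dist, traj.frame_interval_ns))
    return out


def _bound_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end_inclusive) pairs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def merge_runs(
    runs: list[tuple[int, int]], merge_gap_frames: int
) -> list[tuple[int, int]]:
    """Merge consecutive runs separated by strictly fewer than
    ``merge_gap_frames`` frames; the gap frames join the event span."""
    if not runs:
        return []
    merged = [runs[0]]
    for start, end in runs[1:]:
        prev_start, prev_end = merged[-1]
        gap = start - prev_end - 1
        if merge_gap_frames > 0 and gap < merge_gap_frames:
            merged[-1] = (prev_start, end)
        else:
            merged.append((start, end))
    return merged


def detect_events(series: DistanceSeries, config: EventConfig) -> list[BindingEvent]:
    """Threshold + gap-merge event detection on one distance series."""
    mask = series.distances_A <= config.cutoff_A
    return events_from_mask(
        mask,
        config,
        frame_interval_ns=series.frame_interval_ns,
        lipid_id=series.lipid_id,
        residue_key=series.residue_key,
    )


def events_from_mask(
    mask: np.ndarray,
    config: EventConfig,
    frame_interval_ns: float = 1.0,
    lipid_id: str = "",
    residue_key: tuple[str, int] = ("", 0),
) -> list[BindingEvent]:
    """Event detection on a precomputed boolean bound mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty bound mask")
    runs = merge_runs(_bound_runs(mask), config.merge_gap_frames)
    last = len(mask) - 1
    events = []
    for start, end in runs:
        if end - start + 1 < config.min_event_frames:
            continue
        events.append(
            BindingEvent(
                lipid_id=lipid_id,
                residue_key=residue_key,
                start_frame=start,
                end_frame=end,
                duration_ns=(end - start + 1) * frame_interval_ns,
                censored_start=start == 0,
                censored_end=end == last,
            )
        )
    return events


def residence_stats(
    events: list[BindingEvent],
    state_label: str = "",
    residue_keys: list[tuple[str, int]] | None = None,
    include_censored: bool = True,
    pool_chains: bool = True,
) -> list[ResidenceStats]:
    """Aggregate events per residue into N / mean / longest statistics.

    Events from all lipids are pooled; with ``pool_chains`` (default)
    the symmetric subunits of a multimer are pooled under one residue
    number (chain label "*").  Residues listed in ``residue_keys`` with
    no events are reported with N=0 and absent mean/longest.
    """
    if not include_censored:
        events = [e for e in events if not (e.censored_start or e.censored_end)]

    def key_of(k: tuple[str, int]) -> tuple[str, int]:
        return ("*", k[1]) if pool_chains else k

    groups: dict[tuple[str, int], list[float]] = {}
    if residue_keys is not None:
        for k in residue_keys:
            groups.setdefault(key_of(k), [])
    for ev in events:
        groups.setdefault(key_of(ev.residue_key), []).append(ev.duration_ns)
    out = []
    for rkey in groups:
        durs = groups[rkey]
        if durs:
            out.append(
                ResidenceStats(rkey, state_label, len(durs),
                               float(np.mean(durs)), float(np.max(durs)))
            )
        else:
            out.append(ResidenceStats(rkey, state_label, 0, None, None))
    out.sort(key=lambda s: (s.residue_key[1], s.residue_key[0]))
    return out


def events_to_frame(events: list[BindingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lipid": e.lipid_id,
                "chain": e.residue_key[0],
                "residue": e.residue_key[1],
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "duration_ns": e.duration_ns,
                "censored_start": e.censored_start,
                "censored_end": e.censored_end,
            }
            for e in events
        ],
        columns=[
            "lipid", "chain", "residue", "start_frame", "end_frame",
            "duration_ns", "censored_start", "censored_end",
        ],
    )


def stats_to_frame(stats: list[ResidenceStats]) -> pd.DataFrame:
    """Residence table with the standard column order (residue, state,
    total events, mean duration, longest event); absent values print
    as '--'."""
    rows = []
    for s in stats:
        rows.append(
            {
                "residue": f"{s.residue_key[0]}{s.residue_key[1]}"
                if s.residue_key[0] not in ("", "*")
                else str(s.residue_key[1]),
                "state": s.state_label,
                "total_events": s.n_events if s.n_events else "--",
                "mean_duration_ns": round(s.mean_duration_ns, 3)
                if s.mean_duration_ns is not None
                else "--",
                "longest_event_ns": round(s.longest_duration_ns, 3)
                if s.longest_duration_ns is not None
                else "--",
            }
        )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def export_events(
    events: list[BindingEvent],
    stats: list[ResidenceStats],
    events_path: str | Path,
    stats_path: str | Path,
) -> None:
    """Write events and the residence table as TSV."""
    events_to_frame(events).to_csv(events_path, sep="\t", index=False)
    stats_to_frame(stats).to_csv(stats_path, sep="\t", index=False)
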