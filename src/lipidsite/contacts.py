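"""Per-residue lipid contact-number analysis.

A contact is a (lipid heavy atom, residue heavy atom) pair within a
cutoff (default 4 Å, boundary inclusive) in a given frame; the contact
number of a residue in that frame is the count of such pairs, summed
over all lipid copies.  Averaging over frames (zeros included) gives
the average contact number used to rank residues by interaction
strength and persistence.

Two interchangeable engines are provided: a periodic KD-tree
(``method="tree"``) and a brute-force minimum-image pair scan
(``method="brute"``); they agree exactly and the brute-force path
serves as the oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import AtomGroup, Trajectory, min_image_distance_matrix

__all__ = [
    "ContactSeries",
    "ContactSummary",
    "contact_numbers",
    "average_contacts",
    "export_heatmap",
]


@dataclass
class ContactSeries:
    residue_key: tuple[str, int]
    counts: np.ndarray
    cutoff_A: float
    lipid_selection_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")


@dataclass(frozen=True)
class ContactSummary:
    residue_key: tuple[str, int]
    average_contact_number: float
    max_count: int
    fraction_frames_nonzero: float


def _count_pairs_tree(
    lipid: np.ndarray, residue: np.ndarray, cutoff: float, box: np.ndarray | None
) -> int:
    if box is not None:
        lipid = np.mod(lipid, box)
        residue = np.mod(residue, box)
        t1 = cKDTree(lipid, boxsize=box)
        t2 = cKDTree(residue, boxsize=box)
    else:
        t1 = cKDTree(lipid)
        t2 = cKDTree(residue)
    return int(t1.count_neighbors(t2, cutoff))


def _count_pairs_brute(
    lipid: np.ndarray, residue: np.ndarray, cutoff: float, box: np.ndarray | None
) -> int:
    d = min_image_distance_matrix(lipid, residue, box)
    return int((d <= cutoff).sum())


def contact_numbers(
    traj: Trajectory,
    lipid_group: AtomGroup,
    residue_groups: dict[tuple[str, int], AtomGroup],
    cutoff_A: float = 4.0,
    method: str = "tree",
) -> list[ContactSeries]:
    """Per residue, the per-frame count of heavy-atom pairs within
    ``cutoff_A`` between the lipid group and the residue group.

    Hydrogens present in either group are filtered out with a warning
    (the contact definition is heavy-atom only).
    """
    if method not in ("tree", "brute"):
        raise ValueError("method must be 'tree' or 'brute'")
    count = _count_pairs_tree if method == "tree" else _count_pairs_brute

    def ensure_heavy(grp: AtomGroup, what: str) -> AtomGroup:
        heavy = grp.heavy()
        if len(heavy) != len(grp):
            warnings.warn(
                f"{len(grp) - len(heavy)} hydrogen atoms removed from {what}",
                stacklevel=3,
            )
        return heavy

    lipid_group = ensure_heavy(lipid_group, "lipid group")
    if len(lipid_group) == 0:
        raise ValueError("lipid group has no heavy atoms")
    residue_groups = {
        key: ensure_heavy(grp, f"residue {key}") for key, grp in residue_groups.items()
    }
    n_frames = traj.n_frames
    out = {key: np.zeros(n_frames, dtype=np.int64) for key in residue_groups}
    for fi, frame in enumerate(traj.frames):
        lipid_pos = lipid_group.coordinates(frame)
        for key, grp in residue_groups.items():
            if len(grp) == 0:
                continue
            out[key][fi] = count(lipid_pos, grp.coordinates(frame), cutoff_A, frame.box)
    return [
        ContactSeries(key, counts, cutoff_A, lipid_group.label)
        for key, counts in out.items()
    ]


def average_contacts(series: ContactSeries) -> ContactSummary:
    """Time-averaged contact summary (zeros included in the mean)."""
    c = series.counts
    if c.size == 0:
        raise ValueError("empty contact series")
    return ContactSummary(
        residue_key=series.residue_key,
        average_contact_number=float(c.mean()),
        max_count=int(c.max()),
        fraction_frames_nonzero=float((c > 0).mean()),
    )


def contacts_to_frame(series: list[ContactSeries]) -> pd.DataFrame:
    """Residues x frames matrix, rows sorted by average contact number
    descending, with a trailing average column."""
    if not series:
        raise ValueError("no contact series")
    n = {len(s.counts) for s in series}
    if len(n) != 1:
        raise ValueError("contact series must share one frame axis")
    rows = sorted(series, key=lambda s: -s.counts.mean())
    data = {
        f"{s.residue_key[0]}{s.residue_key[1]}": s.counts for s in rows
    }
    df = pd.DataFrame(data).T
    df.columns = [f"frame_{i}" for i in range(df.shape[1])]
    df["average_contact_number"] = [s.counts.mean() for s in rows]
    df.index.name = "residue"
    return df


def export_heatmap(
    series: list[ContactSeries],
    tsv_path: str | Path,
    png_path: str | Path | None = None,
    frame_interval_ns: float | None = None,
) -> pd.DataFrame:
    """Write the contact matrix as TSV and optionally render a heatmap."""
    df = contacts_to_frame(series)
    df.to_csv(tsv_path, sep="\t")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = df.drop(columns="average_contact_number").to_numpy()
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
        im = ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="viridis")
        ax.set_yticks(range(len(df)))
        ax.set_yticklabels(
            [f"{r}  ({a:.2f})" for r, a in zip(df.index, df["average_contact_number"])]
        )
        ax.set_xlabel(
            "frame" if frame_interval_ns is None else
            f"frame (dt = {frame_interval_ns} ns)"
        )
        fig.colorbar(im, ax=ax, label="contact number")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df
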