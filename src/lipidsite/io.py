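"""Structure and trajectory I/O.

PDB, DCD and XTC are handled through MDAnalysis behind the package's own
data model.  A portable plain-text trajectory format (TSV of
``frame  atom_id  x  y  z`` plus a JSON sidecar carrying box, frame
interval and per-frame times) serves as an exact-round-trip exchange
format for fixtures and synthetic data.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import numpy as np

from .core import Frame, Topology, Trajectory, _infer_element

__all__ = [
    "read_structure",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "write_fixture_trajectory",
    "read_fixture_trajectory",
]

FIXTURE_SUFFIXES = {".tsv", ".traj"}


def _mda():
    import MDAnalysis as mda

    return mda


def _universe_from_topology(topology: Topology, coordinates: np.ndarray):
    """Build an in-memory MDAnalysis Universe mirroring our topology."""
    mda = _mda()
    n = topology.n_atoms
    keys = topology.residue_keys()
    key_to_idx = {k: i for i, k in enumerate(keys)}
    atom_resindex = np.array(
        [
            key_to_idx[(str(c), int(r))]
            for c, r in zip(topology.chain_ids, topology.residue_numbers)
        ]
    )
    u = mda.Universe.empty(
        n,
        n_residues=len(keys),
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(len(keys), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.atom_names])
    u.add_TopologyAttr("elements", [str(x) for x in topology.elements])
    u.add_TopologyAttr("resids", [k[1] for k in keys])
    u.add_TopologyAttr(
        "resnames",
        [str(topology.residue_names[topology.residue_atom_ids(c, r)[0]]) for c, r in keys],
    )
    u.add_TopologyAttr("chainIDs", [str(x) or "A" for x in topology.chain_ids])
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
    return u


def read_structure(path: str | os.PathLike) -> tuple[Topology, Frame]:
    """Read a PDB file into a Topology and the first-model coordinates.

    Elements are inferred from atom names when the element column is
    absent.  Only orthorhombic cells are accepted.
    """
    path = Path(path)
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ValueError(f"no atoms found in {path}")
    names = [str(a.name) for a in u.atoms]
    if hasattr(u.atoms, "elements"):
        elements = [str(e).capitalize() if str(e).strip() else _infer_element(n)
                    for e, n in zip(u.atoms.elements, names)]
    else:
        elements = [_infer_element(n) for n in names]
    if hasattr(u.atoms, "chainIDs"):
        chains = [str(c).strip() or "A" for c in u.atoms.chainIDs]
    else:
        chains = [str(a.segid).strip() or "A" for a in u.atoms]
    topology = Topology.from_atoms(
        zip(names, elements, u.atoms.resids, [str(r) for r in u.atoms.resnames], chains)
    )
    box = _box_from_dimensions(u.dimensions)
    frame = Frame(u.atoms.positions.astype(np.float64), box=box, time_ns=0.0)
    return topology, frame


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=np.float64)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {dims[3:]}) not supported; orthorhombic only"
        )
    return dims[:3].copy()


def write_pdb(path: str | os.PathLike, topology: Topology, frame: Frame) -> None:
    """Write a single-model PDB snapshot."""
    u = _universe_from_topology(topology, frame.coordinates)
    if frame.box is not None:
        u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# portable fixture format

def write_fixture_trajectory(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write the portable TSV + JSON-sidecar trajectory format.

    Coordinates are written with repr-level precision so a read-back is
    bit-identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("frame\tatom_id\tx\ty\tz\n")
        for i, fr in enumerate(traj.frames):
            for j, (x, y, z) in enumerate(fr.coordinates.tolist()):
                fh.write(f"{i}\t{j}\t{x!r}\t{y!r}\t{z!r}\n")
    sidecar = {
        "n_atoms": traj.topology.n_atoms,
        "n_frames": traj.n_frames,
        "frame_interval_ns": traj.frame_interval_ns,
        "times_ns": [fr.time_ns for fr in traj.frames],
        "boxes": [None if fr.box is None else list(fr.box) for fr in traj.frames],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_fixture_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    frame_interval_ns: float | None = None,
) -> Trajectory:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    n_atoms = meta["n_atoms"]
    n_frames = meta["n_frames"]
    if n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {n_atoms} atoms but topology has {topology.n_atoms}"
        )
    dt = frame_interval_ns if frame_interval_ns is not None else meta["frame_interval_ns"]
    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float64)
    filled = np.zeros(n_frames, dtype=np.int64)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("frame"):
            raise ValueError(f"malformed fixture trajectory header in {path}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"malformed record at line {lineno} of {path}")
            fi, ai = int(parts[0]), int(parts[1])
            coords[fi, ai] = [float(parts[2]), float(parts[3]), float(parts[4])]
            filled[fi] += 1
    if not np.all(filled == n_atoms):
        bad = int(np.flatnonzero(filled != n_atoms)[0])
        raise IOError(f"truncated trajectory: frame {bad} incomplete in {path}")
    frames = []
    for i in range(n_frames):
        box = meta["boxes"][i]
        t = meta["times_ns"][i] if meta.get("times_ns") else i * dt
        frames.append(Frame(coords[i], box=None if box is None else np.array(box), time_ns=t))
    return Trajectory(topology, frames, dt)


# ---------------------------------------------------------------------------
# binary trajectory formats (DCD / XTC) via MDAnalysis

def read_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    frame_interval_ns: float,
) -> Trajectory:
    """Read a trajectory file (DCD, XTC, or the portable fixture format).

    Frame times are assigned as ``index * frame_interval_ns``; DCD files
    carry no reliable time axis and the fixture sidecar's own times take
    precedence only in the fixture reader.
    """
    path = Path(path)
    if path.suffix in FIXTURE_SUFFIXES:
        return read_fixture_trajectory(path, topology, frame_interval_ns)
    mda = _mda()
    u = _universe_from_topology(topology, np.zeros((topology.n_atoms, 3)))
    try:
        u.load_new(str(path))
    except Exception as exc:
        raise IOError(f"could not read trajectory {path}: {exc}") from exc
    if len(u.trajectory.ts) != topology.n_atoms or u.atoms.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {u.atoms.n_atoms} does not match "
            f"topology ({topology.n_atoms})"
        )
    frames = []
    for i, ts in enumerate(u.trajectory):
        box = _box_from_dimensions(ts.dimensions)
        frames.append(
            Frame(u.atoms.positions.astype(np.float64), box=box,
                  time_ns=i * frame_interval_ns)
        )
    return Trajectory(topology, frames, frame_interval_ns)


def write_trajectory(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write DCD/XTC via MDAnalysis, or the fixture format by suffix."""
    path = Path(path)
    if path.suffix in FIXTURE_SUFFIXES:
        write_fixture_trajectory(path, traj)
        return
    u = _universe_from_topology(traj.topology, traj.frames[0].coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with _mda().Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates.astype(np.float32)
                if fr.box is not None:
                    u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)
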