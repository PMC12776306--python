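import numpy as np
import pytest

from lipidsite.core import Frame, Topology, Trajectory


def pdb_line(serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:<4s}{chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


ARG_ATOMS = [
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
    ("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
    ("CZ", "C"), ("NH1", "N"), ("NH2", "N"),
]


@pytest.fixture
def arg_topology():
    """Arginine 63, glycine 64 and one DHA lipid particle."""
    atoms = [(name, elem, 63, "ARG", "A") for name, elem in ARG_ATOMS]
    atoms += [("N", "N", 64, "GLY", "A"), ("CA", "C", 64, "GLY", "A"),
              ("C", "C", 64, "GLY", "A"), ("O", "O", 64, "GLY", "A")]
    atoms += [("C1", "C", 1, "DHA", "L"), ("O1", "O", 1, "DHA", "L"),
              ("O2", "O", 1, "DHA", "L")]
    return Topology.from_atoms(atoms)


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-atom PDB with two residues, written as literal text."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, "C"),
        pdb_line(3, "C1", "DHA", "L", 2, 8.0, 8.0, 8.0, "C"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_trajectory(topology, coords_per_frame, box=None, dt=1.0):
    frames = [
        Frame(np.asarray(c, dtype=float), box=None if box is None else np.asarray(box, float),
              time_ns=i * dt)
        for i, c in enumerate(coords_per_frame)
    ]
    return Trajectory(topology, frames, dt)


def point_topology(n_points, resname="DHA", chain="L"):
    """n independent single-atom residues (tracer particles)."""
    return Topology.from_atoms(
        [("C1", "C", i + 1, resname, chain) for i in range(n_points)]
    )


def rle_merge_oracle(mask, merge_gap, min_frames=1):
    """Independent run-length-encoding + gap-merge reference used to
    cross-check event detection.  Deliberately written as a plain scan,
    not sharing any code with the implementation."""
    runs = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for start, end in runs:
        if merged and merge_gap > 0 and (start - merged[-1][1] - 1) < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e - s + 1 >= min_frames]
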