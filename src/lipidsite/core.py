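"""Core data model for structures and trajectories.

Coordinates are in Å and times in ns throughout the package.  Boxes are
orthorhombic (three edge lengths); triclinic cells are rejected at read
time.  Atom ids are 0-based and contiguous; residue numbering is 1-based
as in PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "AtomGroup",
    "min_image_displacement",
    "min_image_distance",
    "superpose",
    "PROTEIN_RESNAMES",
    "LIPID_RESNAMES",
    "BACKBONE_NAMES",
]

PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL".split()
)
LIPID_RESNAMES = frozenset(
    "DHA POPC POPE POPG POPS POPA DPPC DOPC DOPE CHL1 LPC LPPC PLM OLE "
    "ARA ETA AGL".split()
)
#: backbone heavy atoms excluded by the ``sidechain`` selection keyword
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})


def _infer_element(atom_name: str) -> str:
    """Element from a PDB-style atom name (first alphabetic character,
    with a two-letter check for common heavy elements)."""
    stripped = atom_name.strip()
    letters = "".join(c for c in stripped if c.isalpha())
    if not letters:
        return "X"
    two = letters[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(stripped) > 1:
        # PDB convention: two-letter elements are left-justified; CA the
        # alpha carbon starts at column 14.  Names passed here have lost
        # column info, so treat CA/CB/etc. as carbon and only accept the
        # unambiguous ions.
        if two in {"CL", "BR", "NA", "MG", "ZN", "FE"} and len(letters) == 2:
            return two.capitalize()
    return letters[0].upper()


def classify_molecule_kind(residue_name: str) -> str:
    name = residue_name.strip().upper()
    if name in PROTEIN_RESNAMES:
        return "protein"
    if name in LIPID_RESNAMES:
        return "lipid"
    return "other"


@dataclass
class Topology:
    """Per-atom annotation table plus a residue index.

    All arrays share one length (the atom count); atom ids are implicit
    array positions, 0-based and contiguous.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    molecule_kinds: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr_name in (
            "atom_names",
            "elements",
            "residue_numbers",
            "residue_names",
            "chain_ids",
            "molecule_kinds",
        ):
            arr = np.asarray(getattr(self, arr_name))
            if len(arr) != n:
                raise ValueError(
                    f"topology field {arr_name} has length {len(arr)}, expected {n}"
                )
            setattr(self, arr_name, arr)
        self.residue_numbers = self.residue_numbers.astype(np.int64)

    @classmethod
    def from_atoms(cls, atoms: Iterable[tuple]) -> "Topology":
        """Build from an iterable of (atom_name, element, residue_number,
        residue_name, chain_id) tuples; element '' means infer from name."""
        names, elems, resids, resnames, chains = [], [], [], [], []
        for name, elem, resid, resname, chain in atoms:
            names.append(name)
            elems.append(elem if elem else _infer_element(name))
            resids.append(int(resid))
            resnames.append(resname)
            chains.append(chain)
        if not names:
            raise ValueError("topology requires at least one atom")
        kinds = [classify_molecule_kind(rn) for rn in resnames]
        return cls(
            np.array(names, dtype=object),
            np.array(elems, dtype=object),
            np.array(resids, dtype=np.int64),
            np.array(resnames, dtype=object),
            np.array(chains, dtype=object),
            np.array(kinds, dtype=object),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_number) keys in order of first atom."""
        seen: dict[tuple[str, int], None] = {}
        for chain, resid in zip(self.chain_ids, self.residue_numbers):
            seen.setdefault((str(chain), int(resid)), None)
        return list(seen)

    def residue_atom_ids(self, chain_id: str, residue_number: int) -> np.ndarray:
        mask = (self.chain_ids == chain_id) & (self.residue_numbers == residue_number)
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One snapshot: n_atoms x 3 coordinates (Å), optional orthorhombic
    box edge lengths (Å) and a time stamp (ns)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (3,):
                raise ValueError("box must be three orthorhombic edge lengths")
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")
        if self.time_ns < 0:
            raise ValueError("time_ns must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(),
                     None if self.box is None else self.box.copy(),
                     self.time_ns)


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    frame_interval_ns: float

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms, topology has {n}"
                )
        times = [fr.time_ns for fr in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coordinates for fr in self.frames])


@dataclass
class AtomGroup:
    """A sorted, duplicate-free set of atom ids tied to a topology."""

    topology: Topology
    atom_ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ids = np.unique(np.asarray(self.atom_ids, dtype=np.int64))
        if len(ids) and (ids[0] < 0 or ids[-1] >= self.topology.n_atoms):
            raise ValueError("atom ids outside topology range")
        self.atom_ids = ids

    def __len__(self) -> int:
        return len(self.atom_ids)

    def coordinates(self, frame: Frame) -> np.ndarray:
        return frame.coordinates[self.atom_ids]

    def heavy(self) -> "AtomGroup":
        """Subset without hydrogens."""
        elems = self.topology.elements[self.atom_ids]
        keep = self.atom_ids[np.array([e != "H" for e in elems])]
        return AtomGroup(self.topology, keep, self.label)


# ---------------------------------------------------------------------------
# geometry

def min_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement components into (-L/2, L/2] per axis."""
    delta = np.asarray(delta, dtype=np.float64)
    if box is None:
        return delta
    box = np.asarray(box, dtype=np.float64)
    return delta - box * np.round(delta / box)


def min_image_distance(p, q, box=None) -> float:
    """Minimum-image distance between two points under an orthorhombic
    box; plain Euclidean distance when box is None."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    if box is not None:
        box = np.asarray(box, dtype=np.float64)
        if not np.all(box > 0):
            raise ValueError("box lengths must be positive")
    d = min_image_displacement(p - q, box)
    return float(np.linalg.norm(d))


def min_image_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(a), len(b))."""
    delta = a[:, None, :] - b[None, :, :]
    delta = min_image_displacement(delta, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t) such that mobile @ R.T + t best
    matches reference.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    A = mobile - mob_c
    B = reference - ref_c
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    return R, t


def superpose(mobile: Frame, reference: Frame, fit_group: AtomGroup) -> Frame:
    """Rigid-body superposition of ``mobile`` onto ``reference`` using the
    fit-group atoms; the transform is applied to every atom and a new
    Frame is returned."""
    ids = fit_group.atom_ids
    if len(ids) < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    mob = mobile.coordinates[ids]
    ref = reference.coordinates[ids]
    if np.linalg.matrix_rank(mob - mob.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear; superposition is degenerate")
    R, t = kabsch(mob, ref)
    out = mobile.copy()
    out.coordinates = mobile.coordinates @ R.T + t
    return out


def fit_rmsd(a: Frame, b: Frame, group: AtomGroup) -> float:
    """RMSD over the group atoms between two frames (no fitting)."""
    d = a.coordinates[group.atom_ids] - b.coordinates[group.atom_ids]
    return float(np.sqrt((d * d).sum() / len(group.atom_ids)))
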