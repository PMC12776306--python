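"""Time-averaged fractional occupancy grids.

The occupancy of a voxel is the fraction of trajectory frames in which
at least one selected atom (typically the lipid carboxylate carbon)
falls inside it — binary per frame, so two atoms in one voxel in one
frame count once.  Values therefore lie in [0, 1]; visualizing at an
iso-threshold of 0.3 highlights regions occupied for at least 30 % of
the trajectory.  Voxel membership uses half-open intervals
``[edge, edge + spacing)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AtomGroup, Frame, Trajectory, superpose

__all__ = [
    "GridSpec",
    "OccupancyGrid",
    "SliceMap",
    "auto_grid_spec",
    "build_occupancy",
    "threshold_voxels",
    "slice_map",
    "write_dx",
    "read_dx",
]


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing_A: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing_A <= 0:
            raise ValueError("spacing_A must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 in each direction")

    @property
    def extent(self) -> np.ndarray:
        """Upper corner of the grid (exclusive)."""
        return np.asarray(self.origin) + self.spacing_A * np.asarray(self.dims)


@dataclass
class OccupancyGrid:
    spec: GridSpec
    values: np.ndarray
    n_frames: int
    selection_label: str = ""
    n_out_of_grid: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.spec.dims):
            raise ValueError("values shape must equal spec.dims")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SliceMap:
    z_level_A: float
    layer_index: int
    values: np.ndarray
    spec: GridSpec


def auto_grid_spec(
    traj: Trajectory,
    selection: AtomGroup,
    spacing_A: float = 1.0,
    margin_A: float = 5.0,
) -> GridSpec:
    """Grid spanning the selection's bounding box over all frames plus a
    margin, at the given spacing."""
    coords = np.concatenate([selection.coordinates(fr) for fr in traj.frames])
    lo = coords.min(axis=0) - margin_A
    hi = coords.max(axis=0) + margin_A
    dims = np.maximum(np.ceil((hi - lo) / spacing_A).astype(int), 1)
    return GridSpec(tuple(float(x) for x in lo), spacing_A, tuple(int(d) for d in dims))


def build_occupancy(
    traj: Trajectory,
    selection: AtomGroup,
    spec: GridSpec | None = None,
    align_group: AtomGroup | None = None,
    spacing_A: float = 1.0,
    margin_A: float = 5.0,
    selection_label: str | None = None,
) -> OccupancyGrid:
    """Fraction-of-frames occupancy grid for the selected atoms.

    With ``align_group``, every frame is first rigid-body superposed
    onto frame 0 using those atoms, removing global protein motion so
    the map lives in a protein-fixed reference frame.  Atoms falling
    outside the grid are tallied (``n_out_of_grid``) and warned about,
    never binned; an auto grid (the default) prevents this.
    """
    if len(selection) == 0:
        raise ValueError("empty selection for occupancy map")
    frames = traj.frames
    if align_group is not None:
        ref = frames[0]
        frames = [ref] + [superpose(fr, ref, align_group) for fr in frames[1:]]
        if spec is None:
            aligned = Trajectory(traj.topology, [f.copy() for f in frames],
                                 traj.frame_interval_ns)
            spec = auto_grid_spec(aligned, selection, spacing_A, margin_A)
    if spec is None:
        spec = auto_grid_spec(traj, selection, spacing_A, margin_A)
    origin = np.asarray(spec.origin)
    dims = np.asarray(spec.dims)
    counts = np.zeros(spec.dims, dtype=np.int64)
    out_of_grid = 0
    for fr in frames:
        pos = selection.coordinates(fr)
        idx = np.floor((pos - origin) / spec.spacing_A).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < dims), axis=1)
        out_of_grid += int((~inside).sum())
        idx = np.unique(idx[inside], axis=0)
        if len(idx):
            counts[idx[:, 0], idx[:, 1], idx[:, 2]] += 1
    if out_of_grid:
        warnings.warn(
            f"{out_of_grid} atom positions fell outside the occupancy grid "
            "and were counted as unoccupied",
            stacklevel=2,
        )
    values = counts / float(len(frames))
    return OccupancyGrid(
        spec,
        values,
        n_frames=len(frames),
        selection_label=selection_label or selection.label,
        n_out_of_grid=out_of_grid,
    )


def threshold_voxels(grid: OccupancyGrid, iso: float = 0.3) -> set[tuple[int, int, int]]:
    """Voxel indices with occupancy >= iso."""
    if not 0.0 <= iso <= 1.0:
        raise ValueError("iso must lie in [0, 1]")
    idx = np.argwhere(grid.values >= iso)
    return {tuple(int(v) for v in row) for row in idx}


def slice_map(grid: OccupancyGrid, z_level_A: float) -> SliceMap:
    """Nearest grid layer to a z level, as a 2D occupancy map."""
    origin_z = grid.spec.origin[2]
    nz = grid.spec.dims[2]
    k = int(round((z_level_A - origin_z) / grid.spec.spacing_A))
    if not (origin_z <= z_level_A <= origin_z + nz * grid.spec.spacing_A):
        raise ValueError(
            f"z = {z_level_A} Å outside grid extent "
            f"[{origin_z}, {origin_z + nz * grid.spec.spacing_A}] Å"
        )
    k = min(max(k, 0), nz - 1)
    return SliceMap(z_level_A, k, grid.values[:, :, k].copy(), grid.spec)


# ---------------------------------------------------------------------------
# OpenDX round trip (via gridData)

def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    from gridData import Grid

    g = Grid(grid.values, origin=np.asarray(grid.spec.origin),
             delta=np.full(3, grid.spec.spacing_A))
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path, n_frames: int = 1) -> OccupancyGrid:
    from gridData import Grid

    try:
        g = Grid(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse OpenDX file {path}: {exc}") from exc
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError("anisotropic OpenDX spacing not supported")
    spec = GridSpec(tuple(float(x) for x in g.origin), float(delta[0]),
                    tuple(int(d) for d in g.grid.shape))
    return OccupancyGrid(spec, np.asarray(g.grid, dtype=np.float64), n_frames=n_frames)
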