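#!/usr/bin/env python
"""Fractional occupancy map of the lipid headgroup around the sites.

Bins the headgroup carbon on a 1 Å grid, writes the OpenDX volume and a
slice through the site plane, and reports how many voxels pass the 0.3
iso-threshold (>= 30 % of frames occupied).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lipidsite.io import read_fixture_trajectory, read_structure
from lipidsite.occupancy import build_occupancy, slice_map, threshold_voxels, write_dx
from lipidsite.select import select

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    topology, _ = read_structure(ROOT / "inputs" / "system.pdb")
    traj = read_fixture_trajectory(ROOT / "inputs" / "trajectory.tsv", topology)
    sel = select(topology, "resname DHA and name C1", label="headgroup carbon")
    grid = build_occupancy(traj, sel)  # auto grid, 1 Å spacing
    outdir = ROOT / "occupancy"
    outdir.mkdir(parents=True, exist_ok=True)
    write_dx(grid, outdir / "occupancy.dx")
    hot = threshold_voxels(grid, 0.3)
    print(f"grid {grid.spec.dims}, spacing {grid.spec.spacing_A} Å, "
          f"{grid.n_frames} frames")
    print(f"max voxel occupancy {grid.values.max():.3f}; "
          f"{len(hot)} voxels at >= 0.3 (the 2 Å bound-state jitter spreads "
          f"each site's density over ~30 voxels, so per-voxel values stay "
          f"well below the site's total occupancy)")
    sm = slice_map(grid, 25.0)  # the anchors' z plane
    np.savetxt(outdir / "slice_z25.tsv", sm.values, delimiter="\t", fmt="%.4f")
    print(f"slice at z = 25 Å (layer {sm.layer_index}) -> slice_z25.tsv; "
          f"slice max {sm.values.max():.3f}")


if __name__ == "__main__":
    main()
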