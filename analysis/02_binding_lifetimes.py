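#!/usr/bin/env python
"""Residence-lifetime analysis of the simulated binding trajectory.

Detects binding events (5 Å sidechain cutoff, gaps of fewer than 10
frames merged) and writes the per-residue residence table — total
events, mean duration and longest event — plus the raw event list,
comparing the recovered mean against the generator's analytic value.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lipidsite.events import (
    EventConfig,
    compute_distance_series,
    detect_events,
    export_events,
    residence_stats,
    stats_to_frame,
)
from lipidsite.io import read_fixture_trajectory, read_structure
from lipidsite.synth import KineticSpec, lipid_groups, site_groups

SEED = 20260919
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec = KineticSpec(seed=SEED)
    topology, _ = read_structure(ROOT / "inputs" / "system.pdb")
    traj = read_fixture_trajectory(ROOT / "inputs" / "trajectory.tsv", topology)
    series = compute_distance_series(
        traj, lipid_groups(spec, topology), site_groups(spec, topology)
    )
    events = [e for s in series for e in detect_events(s, EventConfig())]
    stats = residence_stats(events, state_label="open",
                            residue_keys=[s.residue_key for s in series])
    outdir = ROOT / "binding"
    outdir.mkdir(parents=True, exist_ok=True)
    export_events(events, stats, outdir / "events.tsv",
                  outdir / "residence_stats.tsv")
    print(stats_to_frame(stats).to_string(index=False))
    completed = [e.duration_ns for e in events
                 if not (e.censored_start or e.censored_end)]
    truth = json.loads((ROOT / "inputs" / "ground_truth.json").read_text())
    print(f"\ncompleted events: {len(completed)}; "
          f"mean {np.mean(completed):.1f} ns vs analytic "
          f"{truth['analytic_mean_dwell_ns']:.0f} ns; "
          f"true event count {truth['n_true_events']} vs detected {len(events)}")


if __name__ == "__main__":
    main()
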