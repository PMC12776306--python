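#!/usr/bin/env python
"""Generate the synthetic study inputs.

Simulates the two-state binding system (three symmetric arginine-like
sites on a trimer, 12 lipid headgroup particles, 5000 frames at 1 ns,
mean residence 100 ns) and a set of proton-gated current sweeps across
the activation pH range, writing everything under results/inputs/.
"""

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lipidsite import io as lio
from lipidsite.ephys import write_sweep_csv
from lipidsite.synth import (
    EphysSpec,
    KineticSpec,
    simulate_binding_trajectory,
    simulate_current,
)

SEED = 20260919
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = KineticSpec(seed=SEED)
    traj, truth = simulate_binding_trajectory(spec)
    lio.write_pdb(OUT / "system.pdb", traj.topology, traj.frames[0])
    lio.write_fixture_trajectory(OUT / "trajectory.tsv", traj)
    (OUT / "ground_truth.json").write_text(json.dumps({
        "seed": SEED,
        "analytic_mean_dwell_ns": truth.analytic_mean_dwell_ns,
        "n_true_events": len(truth.events),
        "events": [dataclasses.asdict(e) for e in truth.events],
    }, indent=1))
    print(f"binding trajectory: {traj.n_frames} frames, "
          f"{len(truth.events)} true events "
          f"(analytic mean dwell {truth.analytic_mean_dwell_ns:.0f} ns)")

    espec = EphysSpec(seed=SEED)
    rng = np.random.default_rng(SEED)
    names = []
    for pH in espec.pH_list:
        for sweep in range(espec.n_sweeps):
            trace = simulate_current(espec, pH, rng)
            name = f"sweep_pH{pH:.2f}_{sweep}.csv"
            write_sweep_csv(OUT / name, trace)
            names.append(name)
    (OUT / "sweep_index.json").write_text(json.dumps({
        "seed": SEED, "true_pH05": espec.true_pH05, "true_n": espec.true_n,
        "tau_des_s": espec.tau_des_s, "sweeps": names,
    }, indent=1))
    print(f"current sweeps: {len(names)} files over pH "
          f"{min(espec.pH_list)}..{max(espec.pH_list)} "
          f"(true pH0.5 {espec.true_pH05}, tau_des {espec.tau_des_s} s)")


if __name__ == "__main__":
    main()
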