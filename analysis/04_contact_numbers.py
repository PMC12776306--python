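#!/usr/bin/env python
"""Per-residue contact-number analysis of the simulated trajectory.

Counts lipid-residue heavy-atom pairs within 4 Å per frame, writes the
residues x frames matrix plus a heatmap, and ranks residues by average
contact number.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lipidsite.contacts import average_contacts, contact_numbers, export_heatmap
from lipidsite.io import read_fixture_trajectory, read_structure
from lipidsite.select import select
from lipidsite.synth import KineticSpec, site_groups

SEED = 20260919
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec = KineticSpec(seed=SEED)
    topology, _ = read_structure(ROOT / "inputs" / "system.pdb")
    traj = read_fixture_trajectory(ROOT / "inputs" / "trajectory.tsv", topology)
    lipid = select(topology, "resname DHA and name C1", label="headgroup carbon")
    series = contact_numbers(traj, lipid, site_groups(spec, topology))
    outdir = ROOT / "contacts"
    outdir.mkdir(parents=True, exist_ok=True)
    export_heatmap(series, outdir / "contacts.tsv", outdir / "contacts.png",
                   traj.frame_interval_ns)
    print("residue  avg_contacts  max  frames_nonzero")
    for s in sorted((average_contacts(x) for x in series),
                    key=lambda s: -s.average_contact_number):
        print(f"{s.residue_key[0]}{s.residue_key[1]:<6d} "
              f"{s.average_contact_number:12.3f}  {s.max_count:3d}  "
              f"{s.fraction_frames_nonzero:13.3f}")


if __name__ == "__main__":
    main()
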