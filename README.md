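# lipidsite

Quantitative analysis of how single-acyl-chain lipids (PUFAs such as
docosahexaenoic acid, DHA) engage a membrane protein — here modelled on
the proton-gated channel ASIC3 — combining MD-trajectory analyses with
the patch-clamp readouts used to test those interactions functionally.

**Who it is for.** Anyone who has (a) trajectories of a protein in a
lipid bilayer and wants residence-lifetime tables, occupancy maps and
contact-number fingerprints for a headgroup near candidate residues,
or (b) current sweeps from pH-step protocols and wants desensitization
times, Hill fits of pH activation, and wash-on time courses. A
synthetic-data module generates both kinds of input with exactly known
ground truth, so every analysis is validated end to end.

## The quantities it computes

**Binding events and residence lifetimes.** A lipid headgroup is bound
to a residue in a frame when the minimum distance between the headgroup
atoms and the residue's sidechain heavy atoms is ≤ 5 Å (minimum-image
convention under rectangular periodic boundaries). Maximal runs of
bound frames are events; interruptions of *fewer than* 10 consecutive
frames are merged into one event so brief sub-threshold excursions
("flickers") do not fragment a residence. Per residue the pipeline
reports N (total events), the mean duration and the longest event, in
ns; events touching the trajectory boundaries are flagged censored.

**Occupancy maps.** The fraction of frames in which a selected atom
(by default the carboxylate carbon) occupies each 1 Å voxel — binary
per frame, so values lie in [0, 1] and an iso-surface at 0.3 marks
regions occupied ≥ 30 % of the trajectory. Written as OpenDX plus 2-D
slice maps.

**Contact numbers.** Per residue and frame, the count of heavy-atom
pairs between the lipid group and the residue within 4 Å; averaged over
the trajectory it ranks residues by interaction strength (heatmap +
table).

**Electrophysiology.** Desensitization as the time from the current
peak to its 1/e crossing (≈ 63 % decayed), averaged over sweeps;
pH dose-response normalized to the maximally activating pH 5.5 and
fitted with a Hill-type activation curve restrained to [0, 1],

&nbsp;&nbsp;&nbsp;&nbsp; I(pH) = 1 / (1 + 10^((pH₀.₅ − pH)·n)),

reporting pH₀.₅ (half-maximal activating pH) and the Hill number |n|;
and wash-on time courses normalized to the first sweep.

**Synthetic ground truth.** A frame-discrete two-state kinetic model:
headgroup particles diffuse in a periodic box and bind anchor sites
with per-frame probabilities p_on/p_off, so dwell times are geometric
with mean dt/p_off; optional flickers displace a bound particle just
beyond the cutoff without ending the true event. Current sweeps are
generated as A(pH)·(1 − e^(−t/τ_act))·e^(−t/τ_des) plus Gaussian noise,
with A(pH) from the Hill curve.

## Worked example

The numbered scripts under `analysis/` run the whole study at toy
scale and write their tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_binding_lifetimes.py
python analysis/05_ephys_quantification.py
```

prints (abridged):

```
binding trajectory: 5000 frames, 75 true events (analytic mean dwell 100 ns)

residue state  total_events  mean_duration_ns  longest_event_ns
     63  open            75            94.827             411.0
completed events: 73; mean 91.1 ns vs analytic 100 ns; true event count 75 vs detected 75

pH 5.5 desensitization: mean t_1e = 339 ms over 2 sweeps (generator tau_des 390 ms; ...)
Hill fit: pH0.5 = 6.621 (true 6.6), Hill number = 2.59 (true 3.0)
```

Reading this: the simulator placed three symmetric binding sites
(residue 63 on chains A–C) with a 100 ns mean residence; detection with
the 5 Å / merge-10 rule recovered every one of the 75 true events, and
the residence table's pooled mean (94.8 ns, including two censored
events) sits within sampling error of the analytic value. The Hill fit
recovers the generating midpoint to 0.02 pH units from 16 noisy sweeps
(two per pH, as in a two-sweep-per-condition protocol), and the
measured time-to-1/e at pH 5.5 is slightly below the generator's decay
constant because the 10 ms activation phase delays the peak.

The same computations are available programmatically
(`lipidsite.detect_events`, `build_occupancy`, `contact_numbers`,
`decay_time`, `fit_hill`, …) and through the `lipidsite` CLI
(`lipidsite run config.yaml`, `lipidsite simulate traj|current|suite`,
`lipidsite decay`, `lipidsite hill`).

## Layout

```
src/lipidsite/   core.py      data model, min-image distance, superposition
                 io.py        PDB/DCD/XTC + portable text trajectory format
                 select.py    atom-selection grammar (resid/resname/sidechain/…)
                 events.py    event detection, gap merging, residence tables
                 occupancy.py occupancy grids, iso-threshold, slices, OpenDX
                 contacts.py  contact numbers and heatmaps
                 ephys.py     decay times, Hill fits, wash-on
                 synth.py     kinetic + sweep generators with ground truth
                 pipeline.py  config validation and the report pipeline
                 cli.py       command-line interface
analysis/        numbered drivers reproducing the study at toy scale
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  model assumptions, parameter choices, limitations
```
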