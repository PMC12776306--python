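# Methods

This note records the models implemented in `lipidsite`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions a user should know before
trusting a number.

## Coordinate and time conventions

Coordinates are Å, times ns, currents pA. Boxes are orthorhombic only;
triclinic cells are rejected at read time. Residue numbering is
1-based (PDB convention); atom ids are 0-based and contiguous.
Minimum-image displacements wrap each component into (−L/2, L/2].
Rigid-body superposition uses the Kabsch SVD solution with a
determinant correction against improper rotations; fits with fewer
than three non-collinear atoms are rejected as degenerate.

Binary trajectory formats (DCD/XTC) carry no trustworthy time axis, so
the frame interval is a required user input for them; the package's
portable text format stores it (and per-frame times) in a JSON sidecar
and round-trips coordinates bit-exactly via `repr` precision.

## Binding events and residence statistics

The bound criterion is the minimum over all (headgroup atom, sidechain
heavy atom) pairs of the minimum-image distance, ≤ 5 Å by default and
boundary-inclusive. "Sidechain" means heavy atoms excluding the
backbone N, CA, C, O (and terminal oxygens); glycine therefore has an
empty sidechain and is skipped with a warning. Minimum distance is
used because a single reference point on a sidechain is ambiguous;
the minimum is the standard reading of "within x Å of the sidechain".

Event detection is run-length analysis of the bound mask followed by
gap merging: two runs separated by *strictly fewer than*
`merge_gap_frames` unbound frames (default 10) merge into one event
whose span includes the gap frames; a gap of exactly the threshold
splits. Merging is per (lipid, residue) pair — concurrent visits by
different lipid copies are separate events. Duration is the inclusive
frame count × dt, so a 1-frame event lasts dt, not zero. Events
touching either trajectory boundary are flagged censored; statistics
include them by default with a flag to exclude, since a hard exclusion
would bias against long events. Per-residue tables pool all lipid
copies and (by default) the symmetric subunits of a multimer under one
residue label, with a per-chain breakdown available; the column order
is residue, state, total events, mean duration (ns), longest event
(ns), and residues with no events print `--`.

The merge rule has no intrinsic time scale: 10 frames means different
durations at different save intervals, so the frame interval is
deliberately explicit configuration rather than a guessed default.

## Occupancy maps

Per frame, a voxel is occupied if at least one selected atom falls in
it (half-open intervals [edge, edge + spacing)); the map value is the
occupied-frame fraction, so it is a probability of presence, not a
density — two atoms in one voxel in one frame count once. Default
spacing 1 Å; the display iso-threshold 0.3 marks voxels occupied in at
least 30 % of frames. The default selection is the carboxylate carbon
(the headgroup's interaction centroid); the full carboxylate group is
a one-line selection change. Before binning, frames can be superposed
onto frame 0 via a fit group (protein Cα is the conventional choice)
so the map lives in a protein-fixed reference frame. The auto grid
spans the selection's bounding box over all frames plus a 5 Å margin;
atoms outside an explicit grid are tallied and warned about, never
silently binned.

## Contact numbers

A contact is a (lipid heavy atom, residue heavy atom) pair within
4 Å (inclusive) in a frame; hydrogens are filtered with a warning.
The per-residue average over all frames (zeros included) is the
ranking statistic. Counting uses a periodic KD-tree
(`scipy.spatial.cKDTree` with `boxsize`); a brute-force minimum-image
pair scan is kept as a second engine and the two are asserted equal in
the test suite — the tree is never trusted unchecked.

## Electrophysiology quantification

Analysis works on the baseline-subtracted magnitude of the current
(inward currents are negative by convention), with the baseline taken
as the mean over an annotated pre-pulse window. The peak is the
magnitude extremum after pulse onset; a peak below 3× the baseline SD
is rejected as no response. The desensitization metric is the time
from the peak to the first crossing of peak/e, linearly interpolated
between the bracketing samples to avoid sampling-rate bias; sweeps
that never cross are excluded from experiment averages with their
count reported.

Dose-response points are per-pH mean peaks divided by the response at
the reference pH (5.5, the maximally activating condition), so the
reference point is 1 by construction. The activation curve is

    I(pH) = 1 / (1 + 10^((pH05 − pH) · n))

with asymptotes fixed at 0 and 1 — the fitted curve is bounded in
[0, 1] by construction, which is what "restrained to 0 and 1" means
operationally. As written, a positive n makes I decrease with acidity;
the fit leaves the sign of n free (both initial signs are tried,
keeping the lower SSE, ties broken by smaller |n|) and reports |n| as
the Hill number. pH05 is read directly from the fitted parameter,
which is exactly the pH where the curve equals 0.5. The fit is plain
least squares (Levenberg–Marquardt) and is deterministic for given
data and guesses. Wash-on time courses divide each sweep's peak by the
first sweep's.

## The synthetic generators

**What they emulate.** The kinetic generator reproduces the
*statistical structure* the trajectory analyses assume: tracer
headgroup particles that diffuse in a periodic box (Gaussian steps,
RMS length `unbound_step_A` = 3 Å per frame) and exchange between an
unbound state and site-bound states by per-frame Bernoulli
transitions. Dwell times are therefore geometric with mean
dt/p_off — the frame-discrete analogue of first-order unbinding —
because the downstream analysis is itself frame-discrete. Defaults
mirror the study conditions at toy scale: three symmetric sites
(residue 63 on chains A, B, C of a trimer), 12 tracked lipids in a
50 Å box (a bulk-lipid:tracked-lipid flavour of a 10:1 mixed bilayer),
5000 frames at 1 ns (a 5 μs trajectory), p_off = 0.01/frame giving a
100 ns mean residence — the order of the measured lifetimes at the
arginine cluster — and p_on = 0.5 within a 6 Å capture radius.

**Exact ground truth.** Three constructions make the true event list
recoverable exactly rather than approximately:

1. a bound particle sits within `bound_jitter_A` = 2 Å of its anchor
   (strictly inside the 5 Å detection cutoff, validated), and an
   unbound particle is never inside the cutoff — a particle whose step
   lands inside a capture sphere without binding that frame is clamped
   radially to capture_radius + 10⁻³ Å. Site anchors must be separated
   by more than two capture radii so a clamp near one site cannot land
   inside another's cutoff.
2. after unbinding, a lipid cannot rebind the site it just left for
   `rebind_refractory_frames` (default 10) frames, so genuine
   inter-event gaps are never shorter than the merge threshold and can
   never be fused with the event before them. Re-binding *other*
   sites is unrestricted (those are different lipid–residue pairs).
3. flickers displace a bound particle just beyond the capture radius
   for 1..max_flicker_frames frames without ending the true event;
   p_off is suspended during a flicker, one anchored frame is forced
   after it, and no flicker may start close enough to the trajectory
   end to straddle it. Consequently, detection with merging disabled
   fragments events at every flicker, while merging at any threshold
   above the flicker length and at most the refractory length restores
   the truth exactly.

The refractory period and flicker bookkeeping slightly perturb the
dwell law when flickers are enabled (bound spans lengthen by the
flicker frames); the geometric-law checks therefore run with flickers
disabled.

**What they do not emulate.** No membrane physics: no bilayer, no
inter-lipid interactions, no realistic lipid geometry or
conformational exchange, no force field. One site binds one lipid at
a time. Passing tests therefore demonstrate that the *analysis* is
correct and calibrated — thresholding, merging, censoring, binning,
fitting — not that any particular real system behaves this way.

The sweep generator produces
I(t) = −A(pH)·(1 − e^(−t/τ_act))·e^(−t/τ_des) from pulse onset plus
Gaussian noise, with A(pH) from the Hill curve (true pH05 = 6.6,
|n| = 3, negative sign so response grows with acidity; τ_des = 0.39 s
and a 0.5 s baseline + 2 s pulse at 10 kHz, matching the scale of the
wild-type measurements the analysis is designed for; |n| = 3 is a
typical steepness for proton-gated activation). τ_act = 0 reduces to a
pure monoexponential; with the default 10 ms activation the measured
peak-to-1/e time is slightly below τ_des, which is a property of the
metric, not an error.

## Pipeline and reproducibility

Config validation is strict: unknown keys fail with a spelling
suggestion, every applied default is listed in the summary JSON and
the log, and the parameters with stated conventions default to those
values (5 Å cutoff, merge 10 frames, 1 Å grid, iso 0.3, 4 Å contacts,
reference pH 5.5) while quantities with no defensible default (frame
interval for binary trajectories, the lipid selection, the occupancy
alignment group) must be stated explicitly. All TSV/DX outputs are
written with fixed float formatting so reruns are byte-identical; PNG
heatmaps are excluded from that guarantee (image encoders embed
metadata). All randomness flows through one seeded generator per
simulation, and fixture manifests record seeds and SHA-256 checksums.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make
the statistical assertions meaningful on a single CPU in seconds: the
dwell-recovery runs use 27 sites × 16 000 frames (≈ 1400 completed
events, so the 0.05 KS bound on the geometric law is comfortably
above the ~0.036 sampling noise floor at that n), oracle equivalence
uses 1000 random masks up to 10 000 frames, and Hill recovery uses 200
eight-point dose-response datasets at σ = 0.02.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Event statistics are purely empirical (no survival-curve fitting or
  Markov-state modelling); censored events can be excluded but are not
  otherwise corrected for.
- Occupancy maps are raw per-voxel fractions — no kernel smoothing —
  so values dilute as the selection's positional spread grows relative
  to the voxel size (visible in the toy example, where 2 Å bound
  jitter spreads a site's density over ~30 voxels of a 1 Å grid).
- The Hill fit estimates no confidence intervals; repeat-experiment
  spread is the intended error measure, as in the two-sweep protocol.
- Sweep annotations (baseline window, pulse onset) are user inputs;
  there is no automatic pulse detection or leak subtraction.
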