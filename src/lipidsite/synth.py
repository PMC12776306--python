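"""Synthetic inputs with known ground truth.

Two generators cover everything the analysis pipeline consumes:

* a frame-discrete two-state kinetic model of lipid headgroup particles
  that diffuse in a periodic box and bind to fixed anchor sites
  (emulating, at toy scale, carboxylate headgroups partitioned in a
  10:1 POPC:DHA bilayer binding an arginine cluster on a trimeric
  channel).  Dwell times are geometric — binding and unbinding are
  per-frame Bernoulli transitions — so the analytic mean residence is
  ``frame_interval_ns / p_off``.  Optional "flickers" briefly displace
  a bound particle just beyond the detection cutoff without ending the
  true event, exercising the gap-merging rule.
* proton-gated current sweeps with Hill-distributed peak amplitudes,
  monoexponential (or activation-shaped) kinetics and Gaussian noise.

Both are exactly reproducible from their seed.  The generators target
the statistical structure the analysis assumes (dwell-time law, spatial
proximity, decay shapes); they contain no membrane physics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import AtomGroup, Frame, Topology, Trajectory, min_image_displacement
from .ephys import DoseResponse, SweepTrace, hill_curve
from .events import BindingEvent

__all__ = [
    "Site",
    "KineticSpec",
    "GroundTruth",
    "TrueEvent",
    "EphysSpec",
    "simulate_binding_trajectory",
    "simulate_current",
    "synthetic_dose_response",
    "simulate_dose_response_peaks",
    "write_fixture_suite",
]

_CLAMP_EPS = 1e-3  # Å pushed past the capture radius for excluded particles


@dataclass(frozen=True)
class Site:
    """A binding site: fixed anchor position and per-frame kinetics."""

    anchor: tuple[float, float, float]
    capture_radius_A: float = 6.0
    p_on: float = 0.5
    p_off: float = 0.01
    chain_id: str = "A"
    residue_number: int = 63


def _default_sites() -> tuple[Site, ...]:
    # three symmetric subunit sites, one per chain, same residue label
    return (
        Site((15.0, 25.0, 25.0), chain_id="A"),
        Site((35.0, 15.0, 25.0), chain_id="B"),
        Site((35.0, 35.0, 25.0), chain_id="C"),
    )


@dataclass(frozen=True)
class KineticSpec:
    """Two-state binding simulation parameters.

    Defaults give a toy analogue of the study system: three symmetric
    arginine-like sites on a trimer, a 10:1 bulk:tracked-lipid flavour
    at toy scale (12 headgroup particles), 5000 frames at 1 ns per
    frame (5 μs), and a mean residence of 100 ns (p_off = 0.01/frame).
    """

    n_lipids: int = 12
    n_frames: int = 5000
    frame_interval_ns: float = 1.0
    box: tuple[float, float, float] = (50.0, 50.0, 50.0)
    sites: tuple[Site, ...] = field(default_factory=_default_sites)
    bound_jitter_A: float = 2.0
    flicker_prob: float = 0.0
    max_flicker_frames: int = 0
    unbound_step_A: float = 3.0
    detection_cutoff_A: float = 5.0
    #: frames after an unbinding during which the lipid cannot rebind the
    #: site it just left; keeps true inter-event gaps at least this long,
    #: so gap merging (strictly-shorter-than rule) can never fuse two
    #: genuine events when the merge threshold is <= this value
    rebind_refractory_frames: int = 10
    start_bound: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_lipids < 1:
            raise ValueError("need at least one lipid")
        if not all(l > 0 for l in self.box):
            raise ValueError("box lengths must be positive")
        if self.bound_jitter_A >= self.detection_cutoff_A:
            raise ValueError(
                "bound_jitter_A must be strictly below the detection cutoff "
                "so bound frames are guaranteed within it"
            )
        box = np.asarray(self.box)
        anchors = np.array([s.anchor for s in self.sites])
        for s in self.sites:
            if not (0.0 <= s.p_on <= 1.0 and 0.0 <= s.p_off <= 1.0):
                raise ValueError("p_on/p_off must lie in [0, 1]")
            if s.capture_radius_A < self.detection_cutoff_A:
                raise ValueError(
                    "capture_radius_A must be >= the detection cutoff"
                )
        # capture spheres must not overlap within the detection cutoff,
        # otherwise an excluded particle near one site could sit inside
        # another site's cutoff and break exact ground-truth recovery
        rmax = max((s.capture_radius_A for s in self.sites), default=0.0)
        for i in range(len(anchors)):
            for j in range(i + 1, len(anchors)):
                d = np.linalg.norm(min_image_displacement(anchors[i] - anchors[j], box))
                if d <= 2 * rmax + 2 * _CLAMP_EPS:
                    raise ValueError(
                        f"sites {i} and {j} are {d:.2f} Å apart; need "
                        f"separation > {2 * rmax:.2f} Å"
                    )
        if self.flicker_prob and self.max_flicker_frames < 1:
            raise ValueError("flickering needs max_flicker_frames >= 1")


@dataclass(frozen=True)
class TrueEvent:
    lipid_id: str
    site_index: int
    start_frame: int
    end_frame: int
    censored_start: bool
    censored_end: bool


@dataclass
class GroundTruth:
    events: list[TrueEvent]
    spec: KineticSpec

    @property
    def analytic_mean_dwell_ns(self) -> float:
        p_offs = {s.p_off for s in self.spec.sites}
        if len(p_offs) != 1:
            raise ValueError("sites have differing p_off; no single analytic mean")
        return self.spec.frame_interval_ns / p_offs.pop()

    def completed_durations_ns(self) -> np.ndarray:
        dt = self.spec.frame_interval_ns
        return np.array(
            [
                (e.end_frame - e.start_frame + 1) * dt
                for e in self.events
                if not (e.censored_start or e.censored_end)
            ]
        )

    def to_binding_events(self) -> list[BindingEvent]:
        dt = self.spec.frame_interval_ns
        out = []
        for e in self.events:
            site = self.spec.sites[e.site_index]
            out.append(
                BindingEvent(
                    lipid_id=e.lipid_id,
                    residue_key=(site.chain_id, site.residue_number),
                    start_frame=e.start_frame,
                    end_frame=e.end_frame,
                    duration_ns=(e.end_frame - e.start_frame + 1) * dt,
                    censored_start=e.censored_start,
                    censored_end=e.censored_end,
                )
            )
        return out


def _sim_topology(spec: KineticSpec) -> Topology:
    atoms = []
    for s in spec.sites:
        # one sidechain-labelled heavy atom per anchor pseudo-residue
        atoms.append(("CZ", "C", s.residue_number, "ARG", s.chain_id))
    for i in range(spec.n_lipids):
        atoms.append(("C1", "C", i + 1, "DHA", "L"))
    return Topology.from_atoms(atoms)


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def simulate_binding_trajectory(spec: KineticSpec) -> tuple[Trajectory, GroundTruth]:
    """Run the two-state kinetic model and return the trajectory plus the
    exact ground-truth event list.

    Guarantees used by the downstream analysis: a bound particle is
    always within ``bound_jitter_A`` (< detection cutoff) of its anchor
    except during a flicker, when it sits just beyond the capture
    radius; an unbound particle is never within the capture radius
    (candidates that fail to bind are clamped just outside), so the
    detected bound mask at the detection cutoff equals the true bound
    state apart from flickers.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=np.float64)
    anchors = np.array([s.anchor for s in spec.sites], dtype=np.float64)
    n_sites = len(spec.sites)
    n = spec.n_lipids

    pos = rng.uniform(0.0, box, size=(n, 3))
    bound_site = np.full(n, -1, dtype=np.int64)
    flicker_left = np.zeros(n, dtype=np.int64)
    post_flicker = np.zeros(n, dtype=bool)
    refractory = np.zeros(n, dtype=np.int64)
    refractory_site = np.full(n, -1, dtype=np.int64)
    site_occupant = np.full(n_sites, -1, dtype=np.int64)
    event_start = np.full(n, -1, dtype=np.int64)
    events: list[TrueEvent] = []
    step_sd = spec.unbound_step_A / np.sqrt(3.0)

    def jitter_pos(site_idx: int) -> np.ndarray:
        r = spec.bound_jitter_A * rng.random() ** (1.0 / 3.0)
        return anchors[site_idx] + _random_unit(rng)[0] * r

    def clamp_out(p: np.ndarray, site_idx: int) -> np.ndarray:
        d = min_image_displacement(p - anchors[site_idx], box)
        norm = np.linalg.norm(d)
        unit = d / norm if norm > 0 else _random_unit(rng)[0]
        r = spec.sites[site_idx].capture_radius_A + _CLAMP_EPS
        return np.mod(anchors[site_idx] + unit * r, box)

    if spec.start_bound:
        for i in range(min(n, n_sites)):
            bound_site[i] = i
            site_occupant[i] = i
            pos[i] = jitter_pos(i)
            event_start[i] = 0
    else:
        # make sure nobody starts inside a capture sphere
        for i in range(n):
            d = np.linalg.norm(
                min_image_displacement(pos[i] - anchors, box), axis=1
            )
            j = int(np.argmin(d))
            if d[j] <= spec.sites[j].capture_radius_A:
                pos[i] = clamp_out(pos[i], j)

    frames = [Frame(_assemble(anchors, pos), box=box.copy(), time_ns=0.0)]
    last = spec.n_frames - 1

    for t in range(1, spec.n_frames):
        u_off = rng.random(n)
        u_flick = rng.random(n)
        u_on = rng.random(n)
        steps = rng.normal(scale=step_sd, size=(n, 3))
        for i in range(n):
            s = bound_site[i]
            if s >= 0:
                if flicker_left[i] > 0:
                    flicker_left[i] -= 1
                    pos[i] = clamp_out(anchors[s], s)
                    if flicker_left[i] == 0:
                        post_flicker[i] = True
                    continue
                if post_flicker[i]:
                    # force one anchored frame after a flicker so the true
                    # event never ends on a displaced frame
                    post_flicker[i] = False
                    pos[i] = jitter_pos(s)
                    continue
                if (
                    spec.flicker_prob > 0.0
                    and u_flick[i] < spec.flicker_prob
                    and t + spec.max_flicker_frames < last
                ):
                    k = int(rng.integers(1, spec.max_flicker_frames + 1))
                    flicker_left[i] = k - 1
                    if k == 1:
                        post_flicker[i] = True
                    pos[i] = clamp_out(anchors[s], s)
                    continue
                if u_off[i] < spec.sites[s].p_off:
                    events.append(
                        TrueEvent(
                            f"DHA{i + 1}", int(s), int(event_start[i]), t - 1,
                            censored_start=bool(event_start[i] == 0),
                            censored_end=False,
                        )
                    )
                    bound_site[i] = -1
                    site_occupant[s] = -1
                    event_start[i] = -1
                    refractory[i] = max(spec.rebind_refractory_frames - 1, 0)
                    refractory_site[i] = s
                    pos[i] = clamp_out(anchors[s], s)
                else:
                    pos[i] = jitter_pos(s)
                continue
            # unbound: diffusive step with periodic wrap
            p = np.mod(pos[i] + steps[i], box)
            d = np.linalg.norm(min_image_displacement(p - anchors, box), axis=1)
            j = int(np.argmin(d)) if n_sites else -1
            blocked = refractory[i] > 0
            if blocked:
                refractory[i] -= 1
            if j >= 0 and d[j] <= spec.sites[j].capture_radius_A:
                if blocked and j == refractory_site[i]:
                    pos[i] = clamp_out(p, j)
                elif site_occupant[j] < 0 and u_on[i] < spec.sites[j].p_on:
                    bound_site[i] = j
                    site_occupant[j] = i
                    event_start[i] = t
                    pos[i] = jitter_pos(j)
                else:
                    pos[i] = clamp_out(p, j)
            else:
                pos[i] = p
        frames.append(
            Frame(_assemble(anchors, pos), box=box.copy(),
                  time_ns=t * spec.frame_interval_ns)
        )

    for i in range(n):
        s = bound_site[i]
        if s >= 0:
            events.append(
                TrueEvent(
                    f"DHA{i + 1}", int(s), int(event_start[i]), last,
                    censored_start=bool(event_start[i] == 0),
                    censored_end=True,
                )
            )
    events.sort(key=lambda e: (e.lipid_id, e.start_frame))
    topology = _sim_topology(spec)
    traj = Trajectory(topology, frames, spec.frame_interval_ns)
    return traj, GroundTruth(events, spec)


def _assemble(anchors: np.ndarray, lipid_pos: np.ndarray) -> np.ndarray:
    return np.concatenate([anchors, lipid_pos]) if len(anchors) else lipid_pos.copy()


def site_groups(spec: KineticSpec, topology: Topology) -> dict[tuple[str, int], AtomGroup]:
    """One single-atom 'sidechain' group per anchor pseudo-residue."""
    return {
        (s.chain_id, s.residue_number): AtomGroup(
            topology, np.array([i]), f"{s.chain_id}{s.residue_number}"
        )
        for i, s in enumerate(spec.sites)
    }


def lipid_groups(spec: KineticSpec, topology: Topology) -> dict[str, AtomGroup]:
    n_sites = len(spec.sites)
    return {
        f"DHA{i + 1}": AtomGroup(topology, np.array([n_sites + i]), f"DHA{i + 1}")
        for i in range(spec.n_lipids)
    }


# ---------------------------------------------------------------------------
# synthetic electrophysiology

@dataclass(frozen=True)
class EphysSpec:
    """Synthetic sweep protocol: holding baseline, then an activating
    pulse whose amplitude follows the Hill curve of ``true_pH05`` and
    ``true_n`` (negative n = response grows with acidity)."""

    true_pH05: float = 6.6
    true_n: float = -3.0
    tau_act_s: float = 0.01
    tau_des_s: float = 0.39
    sampling_hz: float = 10_000.0
    noise_sd: float = 0.02  # fraction of the saturating amplitude
    amplitude_pA: float = 500.0
    baseline_s: float = 0.5
    pulse_s: float = 2.0
    pH_list: tuple[float, ...] = (7.0, 6.9, 6.8, 6.7, 6.6, 6.5, 6.2, 5.5)
    n_sweeps: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.tau_des_s <= 0 or self.tau_act_s < 0:
            raise ValueError("time constants must be positive (tau_act may be 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_current(
    spec: EphysSpec, pH: float, rng: np.random.Generator | None = None
) -> SweepTrace:
    """One sweep: noisy baseline, then an inward (negative) current
    ``-A(pH)·(1 - exp(-t/tau_act))·exp(-t/tau_des)`` from pulse onset.
    ``tau_act_s = 0`` gives a pure monoexponential decay from onset."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_hz
    t = np.arange(0.0, spec.baseline_s + spec.pulse_s, dt)
    onset = spec.baseline_s
    amp = spec.amplitude_pA * float(hill_curve(pH, spec.true_pH05, spec.true_n))
    i = np.zeros_like(t)
    pulse = t >= onset
    tp = t[pulse] - onset
    act = 1.0 if spec.tau_act_s == 0 else 1.0 - np.exp(-tp / spec.tau_act_s)
    i[pulse] = -amp * act * np.exp(-tp / spec.tau_des_s)
    if spec.noise_sd > 0:
        i = i + rng.normal(scale=spec.noise_sd * spec.amplitude_pA, size=i.shape)
    return SweepTrace(
        t, i,
        baseline_window_s=(0.0, onset * 0.9),
        pulse_onset_s=onset,
        sweep_id=f"pH{pH}",
        pH=pH,
    )


def synthetic_dose_response(
    true_pH05: float = 6.6,
    true_n: float = -3.0,
    pHs: tuple[float, ...] = (7.0, 6.9, 6.8, 6.7, 6.6, 6.5, 6.2, 5.5),
    noise_sd: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> DoseResponse:
    """Normalized dose-response points drawn from the Hill curve with
    additive Gaussian noise (the reference point is pinned to 1)."""
    rng = np.random.default_rng(rng)
    ys = hill_curve(np.asarray(pHs), true_pH05, true_n)
    ys = ys + rng.normal(scale=noise_sd, size=ys.shape)
    pts = [(float(p), float(y)) for p, y in zip(pHs, ys)]
    return DoseResponse(pts, reference_pH=5.5 if 5.5 in pHs else float(min(pHs)))


def simulate_dose_response_peaks(
    spec: EphysSpec, rng: np.random.Generator | None = None
) -> list[tuple[float, float]]:
    """Full sweep-level protocol: per pH, ``n_sweeps`` sweeps are
    simulated, their baseline-subtracted peak magnitudes measured and
    averaged."""
    from .ephys import decay_time

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = []
    for pH in spec.pH_list:
        peaks = []
        for _ in range(spec.n_sweeps):
            trace = simulate_current(spec, pH, rng)
            peaks.append(decay_time(trace).peak_amplitude)
        out.append((float(pH), float(np.mean(peaks))))
    return out


# ---------------------------------------------------------------------------
# fixture suite

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Emit a small deterministic fixture set (toy structure, portable
    trajectory, sweep CSVs, residence table) plus a manifest recording
    the seed and a checksum per file."""
    from . import io as lio
    from .events import EventConfig, detect_events, export_events, residence_stats
    from .events import compute_distance_series

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = KineticSpec(n_lipids=4, n_frames=300, seed=seed)
    traj, truth = simulate_binding_trajectory(spec)
    lio.write_pdb(outdir / "toy_system.pdb", traj.topology, traj.frames[0])
    lio.write_fixture_trajectory(outdir / "toy_trajectory.tsv", traj)
    series = compute_distance_series(
        traj, lipid_groups(spec, traj.topology), site_groups(spec, traj.topology)
    )
    cfg = EventConfig()
    events = [e for s in series for e in detect_events(s, cfg)]
    stats = residence_stats(events, state_label="open",
                            residue_keys=[s.residue_key for s in series])
    export_events(events, stats, outdir / "events.tsv", outdir / "residence_stats.tsv")
    espec = EphysSpec(seed=seed)
    rng = np.random.default_rng(seed)
    from .ephys import write_sweep_csv

    sweep_files = []
    for pH in (6.6, 5.5):
        trace = simulate_current(espec, pH, rng)
        name = f"sweep_pH{pH:.1f}.csv"
        write_sweep_csv(outdir / name, trace)
        sweep_files.extend([name, name + ".json"])
    files = [
        "toy_system.pdb",
        "toy_trajectory.tsv",
        "toy_trajectory.tsv.json",
        "events.tsv",
        "residence_stats.tsv",
        *sweep_files,
    ]
    manifest = {
        "seed": seed,
        "kinetic_spec": {"n_lipids": spec.n_lipids, "n_frames": spec.n_frames},
        "files": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
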