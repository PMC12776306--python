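"""Configuration, validation and the end-to-end report pipeline.

The pipeline runs distance → events → residence statistics, then (if
their config sections are present) the occupancy map, contact analysis
and electrophysiology summaries, writing TSV/OpenDX/PNG outputs plus a
machine-readable ``summary.json`` into one output directory.

Validation is strict: unknown keys are rejected (with a spelling
suggestion), every applied default is listed in the summary, and
quantities the analysis cannot guess (frame interval for binary
trajectories, the lipid atom selection, the occupancy alignment group)
must be stated explicitly.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import AtomGroup, Trajectory
from .contacts import average_contacts, contact_numbers, export_heatmap
from .ephys import (
    average_sweeps,
    decay_time,
    fit_hill,
    normalize_dose_response,
    read_sweep_csv,
    washon_timecourse,
)
from .events import (
    EventConfig,
    compute_distance_series,
    detect_events,
    export_events,
    residence_stats,
)
from .io import FIXTURE_SUFFIXES, read_structure, read_trajectory
from .occupancy import build_occupancy, slice_map, threshold_voxels, write_dx
from .select import select

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("lipidsite")


class ConfigError(ValueError):
    pass


_TOP_KEYS = {
    "topology", "trajectory", "frame_interval_ns", "lipid_selection",
    "residues", "chains", "state_label", "events", "occupancy",
    "contacts", "ephys", "output_dir", "seed", "log_level",
    "include_censored", "pool_chains",
}
_EVENT_KEYS = {"cutoff_A", "merge_gap_frames", "min_event_frames"}
_OCC_KEYS = {"selection", "spacing_A", "iso", "margin_A", "align", "slice_z_A"}
_CONTACT_KEYS = {"lipid_selection", "cutoff_A", "residues"}
_EPHYS_KEYS = {"sweeps", "dose_response", "washon_peaks", "reference_pH"}

#: defaults mirroring the stated analysis parameters
DEFAULTS = {
    "events.cutoff_A": 5.0,
    "events.merge_gap_frames": 10,
    "events.min_event_frames": 1,
    "occupancy.spacing_A": 1.0,
    "occupancy.iso": 0.3,
    "occupancy.margin_A": 5.0,
    "contacts.cutoff_A": 4.0,
    "ephys.reference_pH": 5.5,
}


@dataclass
class RunConfig:
    topology: Path
    trajectory: Path
    lipid_selection: str
    residues: list[int]
    frame_interval_ns: float | None = None
    chains: list[str] | None = None
    state_label: str = ""
    events: EventConfig = field(default_factory=EventConfig)
    occupancy: dict | None = None
    contacts: dict | None = None
    ephys: dict | None = None
    output_dir: Path = Path("lipidsite_out")
    seed: int = 0
    log_level: str = "INFO"
    include_censored: bool = True
    pool_chains: bool = True
    defaults_applied: list[str] = field(default_factory=list)


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {where}{extra}")


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML/JSON config file (or a dict)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {source} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    defaults_applied: list[str] = []

    for req in ("topology", "trajectory", "lipid_selection", "residues"):
        if req not in raw:
            raise ConfigError(f"missing required config key {req!r}")
    topology = Path(raw["topology"])
    trajectory = Path(raw["trajectory"])
    for p in (topology, trajectory):
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
    dt = raw.get("frame_interval_ns")
    if dt is None and trajectory.suffix not in FIXTURE_SUFFIXES:
        raise ConfigError(
            "frame_interval_ns is required for binary trajectories "
            "(the file carries no time axis)"
        )
    if dt is not None and dt <= 0:
        raise ConfigError("frame_interval_ns must be positive")

    ev_raw = raw.get("events", {}) or {}
    _check_keys(ev_raw, _EVENT_KEYS, "events")
    ev_kwargs = {}
    for key in _EVENT_KEYS:
        if key in ev_raw:
            ev_kwargs[key] = ev_raw[key]
        else:
            ev_kwargs[key] = DEFAULTS[f"events.{key}"]
            defaults_applied.append(f"events.{key} = {ev_kwargs[key]}")
    try:
        events = EventConfig(**ev_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    occ = raw.get("occupancy")
    if occ is not None:
        occ = dict(occ)
        _check_keys(occ, _OCC_KEYS, "occupancy")
        if "align" not in occ:
            raise ConfigError(
                "occupancy.align must be stated explicitly (a selection "
                "expression, or null for no alignment)"
            )
        for key in ("spacing_A", "iso", "margin_A"):
            if key not in occ:
                occ[key] = DEFAULTS[f"occupancy.{key}"]
                defaults_applied.append(f"occupancy.{key} = {occ[key]}")
        if not 0 <= occ["iso"] <= 1:
            raise ConfigError("occupancy.iso must lie in [0, 1]")
        if occ["spacing_A"] <= 0:
            raise ConfigError("occupancy.spacing_A must be positive")

    con = raw.get("contacts")
    if con is not None:
        con = dict(con)
        _check_keys(con, _CONTACT_KEYS, "contacts")
        if "lipid_selection" not in con:
            raise ConfigError(
                "contacts.lipid_selection must be stated explicitly (e.g. the "
                "carboxylate carbon or the full carboxylate group)"
            )
        if "cutoff_A" not in con:
            con["cutoff_A"] = DEFAULTS["contacts.cutoff_A"]
            defaults_applied.append(f"contacts.cutoff_A = {con['cutoff_A']}")
        if con["cutoff_A"] <= 0:
            raise ConfigError("contacts.cutoff_A must be positive")

    eph = raw.get("ephys")
    if eph is not None:
        eph = dict(eph)
        _check_keys(eph, _EPHYS_KEYS, "ephys")
        if "reference_pH" not in eph:
            eph["reference_pH"] = DEFAULTS["ephys.reference_pH"]
            defaults_applied.append(f"ephys.reference_pH = {eph['reference_pH']}")
        for sweep in eph.get("sweeps", []):
            if not Path(sweep).exists():
                raise ConfigError(f"sweep file not found: {sweep}")

    cfg = RunConfig(
        topology=topology,
        trajectory=trajectory,
        lipid_selection=str(raw["lipid_selection"]),
        residues=[int(r) for r in raw["residues"]],
        frame_interval_ns=dt,
        chains=list(raw["chains"]) if raw.get("chains") else None,
        state_label=str(raw.get("state_label", "")),
        events=events,
        occupancy=occ,
        contacts=con,
        ephys=eph,
        output_dir=Path(raw.get("output_dir", "lipidsite_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        include_censored=bool(raw.get("include_censored", True)),
        pool_chains=bool(raw.get("pool_chains", True)),
        defaults_applied=defaults_applied,
    )
    return cfg


def _per_lipid_groups(topology, lipid_sel: str) -> dict[str, AtomGroup]:
    grp = select(topology, lipid_sel, label="lipid")
    out: dict[str, AtomGroup] = {}
    for aid in grp.atom_ids:
        chain = str(topology.chain_ids[aid])
        resid = int(topology.residue_numbers[aid])
        resname = str(topology.residue_names[aid])
        key = f"{resname}{resid}"
        out.setdefault(key, []).append(aid)
    return {
        k: AtomGroup(topology, np.array(ids), k) for k, ids in out.items()
    }


def _residue_groups(topology, residues, chains) -> dict[tuple[str, int], AtomGroup]:
    out = {}
    for chain, resid in topology.residue_keys():
        if resid not in residues:
            continue
        if chains is not None and chain not in chains:
            continue
        grp = select(topology, f"chain {chain} and resid {resid} and sidechain",
                     label=f"{chain}{resid}")
        out[(chain, resid)] = grp
    missing = set(residues) - {r for _, r in out}
    if missing:
        raise ConfigError(f"residues not found in topology: {sorted(missing)}")
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage and write the report directory."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    summary: dict = {
        "lipidsite_version": __version__,
        "seed": config.seed,
        "defaults_applied": config.defaults_applied,
        "stages": {},
    }
    for line in config.defaults_applied:
        logger.info("default applied: %s", line)
    try:
        topology, _frame0 = read_structure(config.topology)
        traj = read_trajectory(
            config.trajectory, topology,
            config.frame_interval_ns if config.frame_interval_ns else 1.0,
        )
        if config.trajectory.suffix in FIXTURE_SUFFIXES and config.frame_interval_ns:
            traj = Trajectory(topology, traj.frames, config.frame_interval_ns)
        logger.info("trajectory: %d frames, %d atoms, dt = %g ns",
                    traj.n_frames, topology.n_atoms, traj.frame_interval_ns)

        lipids = _per_lipid_groups(topology, config.lipid_selection)
        res_groups = _residue_groups(topology, config.residues, config.chains)
        series = compute_distance_series(traj, lipids, res_groups)
        all_events = [e for s in series for e in detect_events(s, config.events)]
        stats = residence_stats(
            all_events,
            state_label=config.state_label,
            residue_keys=[s.residue_key for s in series],
            include_censored=config.include_censored,
            pool_chains=config.pool_chains,
        )
        export_events(all_events, stats,
                      outdir / "events.tsv", outdir / "residence_stats.tsv")
        summary["stages"]["events"] = {
            "n_events": len(all_events),
            "n_pairs": len(series),
            "cutoff_A": config.events.cutoff_A,
            "merge_gap_frames": config.events.merge_gap_frames,
        }
        logger.info("events: %d events over %d pairs", len(all_events), len(series))

        if config.occupancy is not None:
            occ_cfg = config.occupancy
            sel = select(topology, occ_cfg.get("selection") or config.lipid_selection,
                         label="occupancy selection")
            align = (
                select(topology, occ_cfg["align"], label="align")
                if occ_cfg.get("align")
                else None
            )
            grid = build_occupancy(
                traj, sel, align_group=align,
                spacing_A=occ_cfg["spacing_A"], margin_A=occ_cfg["margin_A"],
            )
            write_dx(grid, outdir / "occupancy.dx")
            n_iso = len(threshold_voxels(grid, occ_cfg["iso"]))
            if occ_cfg.get("slice_z_A") is not None:
                sm = slice_map(grid, float(occ_cfg["slice_z_A"]))
                np.savetxt(outdir / "occupancy_slice.tsv", sm.values,
                           delimiter="\t", fmt="%.6f")
            summary["stages"]["occupancy"] = {
                "n_frames": grid.n_frames,
                "iso": occ_cfg["iso"],
                "n_voxels_at_iso": n_iso,
                "max_occupancy": float(grid.values.max()),
            }
            logger.info("occupancy: %d voxels >= iso %.2f", n_iso, occ_cfg["iso"])

        if config.contacts is not None:
            con_cfg = config.contacts
            lipid_grp = select(topology, con_cfg["lipid_selection"], label="contact lipid")
            con_res = _residue_groups(
                topology, con_cfg.get("residues") or config.residues, config.chains
            )
            cseries = contact_numbers(traj, lipid_grp, con_res,
                                      cutoff_A=con_cfg["cutoff_A"])
            export_heatmap(cseries, outdir / "contacts.tsv",
                           outdir / "contacts.png", traj.frame_interval_ns)
            summaries = sorted(
                (average_contacts(s) for s in cseries),
                key=lambda s: -s.average_contact_number,
            )
            with open(outdir / "contact_summary.tsv", "w") as fh:
                fh.write("residue\taverage_contact_number\tmax_count\t"
                         "fraction_frames_nonzero\n")
                for s in summaries:
                    fh.write(
                        f"{s.residue_key[0]}{s.residue_key[1]}\t"
                        f"{s.average_contact_number:.6f}\t{s.max_count}\t"
                        f"{s.fraction_frames_nonzero:.6f}\n"
                    )
            summary["stages"]["contacts"] = {
                "cutoff_A": con_cfg["cutoff_A"],
                "top_residue": f"{summaries[0].residue_key[0]}"
                               f"{summaries[0].residue_key[1]}",
                "top_average": summaries[0].average_contact_number,
            }

        if config.ephys is not None:
            _run_ephys(config.ephys, outdir, summary)
    except Exception:
        logger.exception("pipeline stage failed")
        logger.removeHandler(handler)
        handler.close()
        raise
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return outdir


def _run_ephys(eph: dict, outdir: Path, summary: dict) -> None:
    stage: dict = {}
    if eph.get("sweeps"):
        results = []
        with open(outdir / "decay.tsv", "w") as fh:
            fh.write("sweep\tpeak_time_s\tpeak_amplitude\tt_1e_s\tcrossed\n")
            for path in eph["sweeps"]:
                trace = read_sweep_csv(path)
                r = decay_time(trace)
                results.append(r)
                fh.write(
                    f"{trace.sweep_id or Path(path).stem}\t{r.peak_time_s:.6f}\t"
                    f"{r.peak_amplitude:.6f}\t"
                    f"{'' if r.t_1e_s is None else format(r.t_1e_s, '.6f')}\t"
                    f"{r.crossed}\n"
                )
        avg = average_sweeps(results)
        stage["mean_t_1e_s"] = avg.mean_t_1e_s
        stage["n_sweeps_excluded"] = avg.n_excluded
    if eph.get("dose_response"):
        import pandas as pd

        df = pd.read_csv(eph["dose_response"])
        peaks = list(zip(df["pH"], df["peak"]))
        dr = normalize_dose_response(peaks, reference_pH=eph["reference_pH"])
        fit = fit_hill(dr)
        with open(outdir / "dose_response.tsv", "w") as fh:
            fh.write("pH\tnormalized_response\tfit\n")
            for pH, y in dr.points:
                fh.write(f"{pH}\t{y:.6f}\t{float(fit.predict(pH)):.6f}\n")
        with open(outdir / "hill_fits.tsv", "w") as fh:
            fh.write("pH05\thill_number\tn_signed\tresidual_sse\tconverged\n")
            fh.write(f"{fit.pH05:.6f}\t{fit.hill_number:.6f}\t{fit.n:.6f}\t"
                     f"{fit.residual_sse:.6e}\t{fit.converged}\n")
        stage["pH05"] = fit.pH05
        stage["hill_number"] = fit.hill_number
    if eph.get("washon_peaks"):
        tc = washon_timecourse([float(x) for x in eph["washon_peaks"]])
        with open(outdir / "timecourse.tsv", "w") as fh:
            fh.write("sweep\tnormalized_peak\n")
            for i, v in enumerate(tc.normalized_peaks, start=1):
                fh.write(f"{i}\t{v:.6f}\n")
        stage["washon_final_ratio"] = float(tc.normalized_peaks[-1])
    summary["stages"]["ephys"] = stage
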