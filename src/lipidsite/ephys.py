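"""Patch-clamp trace quantification.

Implements the functional readouts used to characterise proton-gated
currents and their modulation by lipids:

* desensitization rate as the time from the current peak to its 1/e
  crossing (the point where ~63 % of the peak has decayed), averaged
  over sweeps;
* pH dose-response normalized to the maximally activating reference pH
  (5.5) and fitted with a Hill-type curve

      I(pH) = 1 / (1 + 10**((pH05 - pH) * n))

  whose asymptotes are fixed at 0 and 1 (the curve is restrained to
  [0, 1] by construction) and whose midpoint pH05 is the half-maximal
  activating pH;
* wash-on time courses, each sweep's peak normalized to the first
  sweep.

Sign convention: inward currents are negative; analysis works on the
baseline-subtracted magnitude, so no user sign flips are needed.  In
the Hill form above a *negative* n gives a response that grows with
acidity; the fit leaves the sign of n free and ``HillFit.hill_number``
reports |n|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SweepTrace",
    "DecayResult",
    "AverageDecay",
    "DoseResponse",
    "HillFit",
    "TimeCourse",
    "hill_curve",
    "decay_time",
    "average_sweeps",
    "normalize_dose_response",
    "fit_hill",
    "washon_timecourse",
    "read_sweep_csv",
    "write_sweep_csv",
]


@dataclass
class SweepTrace:
    """One recorded sweep: time (s), current (pA), and annotations
    locating the pre-pulse baseline window and the agonist pulse."""

    time_s: np.ndarray
    current: np.ndarray
    baseline_window_s: tuple[float, float]
    pulse_onset_s: float
    sweep_id: str = ""
    condition: str = ""
    pH: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.time_s.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.baseline_window_s[1] <= self.pulse_onset_s:
            raise ValueError("baseline window must precede pulse onset")


@dataclass(frozen=True)
class DecayResult:
    peak_time_s: float
    peak_amplitude: float
    t_1e_s: float | None
    crossed: bool
    baseline: float = 0.0


@dataclass(frozen=True)
class AverageDecay:
    mean_t_1e_s: float | None
    n_crossed: int
    n_excluded: int


@dataclass
class DoseResponse:
    points: list[tuple[float, float]]  # (pH, normalized response)
    reference_pH: float = 5.5


@dataclass(frozen=True)
class HillFit:
    pH05: float
    n: float
    residual_sse: float
    converged: bool

    @property
    def hill_number(self) -> float:
        """Magnitude of the Hill coefficient."""
        return abs(self.n)

    def predict(self, pH) -> np.ndarray:
        return hill_curve(np.asarray(pH, dtype=np.float64), self.pH05, self.n)


@dataclass
class TimeCourse:
    normalized_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.normalized_peaks = np.asarray(self.normalized_peaks, dtype=np.float64)
        if self.normalized_peaks[0] != 1.0:
            raise ValueError("first sweep must normalize to 1")


def hill_curve(pH, pH05: float, n: float):
    """Hill-type activation curve with asymptotes fixed at 0 and 1."""
    return 1.0 / (1.0 + 10.0 ** ((pH05 - np.asarray(pH, dtype=np.float64)) * n))


def decay_time(trace: SweepTrace) -> DecayResult:
    """Time from the current peak to the 1/e crossing.

    Baseline is the mean current over the annotated window; the peak is
    the extremum of the baseline-subtracted magnitude after pulse onset;
    the crossing time is linearly interpolated between the bracketing
    samples.  ``crossed`` is False when the trace never decays to
    peak/e within the sweep.
    """
    t, i = trace.time_s, trace.current
    b0, b1 = trace.baseline_window_s
    base_mask = (t >= b0) & (t <= b1)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(i[base_mask].mean())
    base_sd = float(i[base_mask].std())
    after = np.flatnonzero(t >= trace.pulse_onset_s)
    if len(after) < 3:
        raise ValueError("too few samples after pulse onset")
    mag = np.abs(i[after] - baseline)
    peak_local = int(np.argmax(mag))
    peak_amp = float(mag[peak_local])
    if peak_amp < 3.0 * base_sd or peak_amp == 0.0:
        raise ValueError(
            f"no peak above noise (amplitude {peak_amp:.3g}, "
            f"baseline SD {base_sd:.3g})"
        )
    peak_idx = after[peak_local]
    peak_time = float(t[peak_idx])
    target = peak_amp / math.e
    seg = np.abs(i[peak_idx:] - baseline)
    seg_t = t[peak_idx:]
    below = np.flatnonzero(seg <= target)
    below = below[below > 0]
    if len(below) == 0:
        return DecayResult(peak_time, peak_amp, None, False, baseline)
    k = int(below[0])
    # linear interpolation between the bracketing samples
    y0, y1 = seg[k - 1], seg[k]
    t0, t1 = seg_t[k - 1], seg_t[k]
    frac = 0.0 if y0 == y1 else (y0 - target) / (y0 - y1)
    t_cross = float(t0 + frac * (t1 - t0))
    return DecayResult(peak_time, peak_amp, t_cross - peak_time, True, baseline)


def average_sweeps(results: list[DecayResult]) -> AverageDecay:
    """Mean 1/e decay time over crossed sweeps; uncrossed sweeps are
    excluded and counted."""
    crossed = [r.t_1e_s for r in results if r.crossed]
    n_excluded = len(results) - len(crossed)
    if not crossed:
        return AverageDecay(None, 0, n_excluded)
    return AverageDecay(float(np.mean(crossed)), len(crossed), n_excluded)


def normalize_dose_response(
    peaks: list[tuple[float, float]], reference_pH: float = 5.5
) -> DoseResponse:
    """Divide each (pH, peak) response by the response at the reference
    pH (the maximally activating condition)."""
    ref = [p for pH, p in peaks if pH == reference_pH]
    if not ref:
        raise ValueError(f"reference pH {reference_pH} missing from dose-response data")
    ref_amp = float(np.mean(ref))
    if ref_amp <= 0:
        raise ValueError("reference response must be positive")
    return DoseResponse(
        [(float(pH), float(p) / ref_amp) for pH, p in peaks], reference_pH
    )


def fit_hill(
    dr: DoseResponse,
    initial_pH05: float | None = None,
    initial_n: float | None = None,
) -> HillFit:
    """Least-squares Hill fit with asymptotes fixed at 0 and 1.

    By default both signs of the initial Hill coefficient (+1 and -1)
    are tried and the fit with lower SSE is kept (ties broken by lower
    |n|), making the result deterministic for given data and guesses.
    """
    pHs = np.array([p for p, _ in dr.points])
    ys = np.array([y for _, y in dr.points])
    if len(np.unique(pHs)) < 4:
        raise ValueError("need at least 4 distinct pH points for a Hill fit")
    if np.ptp(ys) < 1e-12:
        raise ValueError("degenerate dose-response: all responses equal")
    p0_mid = initial_pH05 if initial_pH05 is not None else float(pHs.mean())
    n_starts = [initial_n] if initial_n is not None else [1.0, -1.0]

    def resid(params):
        return hill_curve(pHs, params[0], params[1]) - ys

    best = None
    for n0 in n_starts:
        sol = least_squares(resid, x0=[p0_mid, n0], method="lm", max_nfev=10000)
        sse = float(np.sum(sol.fun**2))
        cand = (sse, abs(sol.x[1]), sol)
        if best is None or cand[:2] < best[:2]:
            best = cand
    sse, _, sol = best
    return HillFit(float(sol.x[0]), float(sol.x[1]), sse, bool(sol.success))


def washon_timecourse(peaks: list[float]) -> TimeCourse:
    """Per-sweep peaks normalized to the first sweep."""
    if len(peaks) == 0:
        raise ValueError("need at least one sweep")
    first = float(peaks[0])
    if first <= 0:
        raise ValueError("first-sweep peak must be positive")
    return TimeCourse(np.asarray(peaks, dtype=np.float64) / first)


# ---------------------------------------------------------------------------
# sweep CSV I/O

def write_sweep_csv(path: str | Path, trace: SweepTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current}).to_csv(
        path, index=False
    )
    import json

    meta = {
        "baseline_window_s": list(trace.baseline_window_s),
        "pulse_onset_s": trace.pulse_onset_s,
        "sweep_id": trace.sweep_id,
        "condition": trace.condition,
        "pH": trace.pH,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_sweep_csv(path: str | Path) -> SweepTrace:
    import json

    df = pd.read_csv(path)
    if "time_s" not in df or "current_pA" not in df:
        raise ValueError(f"{path} must have time_s and current_pA columns")
    meta_path = Path(str(path) + ".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing annotation sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return SweepTrace(
        df["time_s"].to_numpy(),
        df["current_pA"].to_numpy(),
        tuple(meta["baseline_window_s"]),
        meta["pulse_onset_s"],
        meta.get("sweep_id", ""),
        meta.get("condition", ""),
        meta.get("pH"),
    )
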