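"""Desensitization timing, dose-response normalization, Hill fits and
wash-on time courses."""

import numpy as np
import pytest
from scipy.optimize import brentq

from lipidsite.ephys import (
    DoseResponse,
    SweepTrace,
    average_sweeps,
    decay_time,
    fit_hill,
    hill_curve,
    normalize_dose_response,
    read_sweep_csv,
    washon_timecourse,
    write_sweep_csv,
)


def exp_decay_trace(tau=0.39, amp=-500.0, fs=10_000.0, baseline_s=0.2, pulse_s=2.0):
    dt = 1.0 / fs
    t = np.arange(0.0, baseline_s + pulse_s, dt)
    i = np.zeros_like(t)
    mask = t >= baseline_s
    i[mask] = amp * np.exp(-(t[mask] - baseline_s) / tau)
    return SweepTrace(t, i, (0.0, baseline_s * 0.9), baseline_s)


class TestDecayTime:
    def test_monoexponential_within_one_sample(self):
        r = decay_time(exp_decay_trace(tau=0.39))
        assert r.crossed
        assert abs(r.t_1e_s - 0.39) <= 1e-4  # one sample at 10 kHz

    def test_scale_invariance(self):
        for amp in (-50.0, -2000.0, 300.0):
            for tau in (0.05, 0.39, 1.2):
                r = decay_time(exp_decay_trace(tau=tau, amp=amp))
                assert abs(r.t_1e_s - tau) <= 1e-4

    def test_never_crosses(self):
        trace = exp_decay_trace(tau=50.0, pulse_s=1.0)
        r = decay_time(trace)
        assert not r.crossed and r.t_1e_s is None

    def test_biexponential_matches_root_finding_oracle(self):
        a1, tau1, a2, tau2 = 300.0, 0.1, 200.0, 0.8
        fs, onset = 10_000.0, 0.2
        t = np.arange(0.0, 3.0, 1.0 / fs)
        i = np.zeros_like(t)
        mask = t >= onset
        tp = t[mask] - onset
        i[mask] = -(a1 * np.exp(-tp / tau1) + a2 * np.exp(-tp / tau2))
        r = decay_time(SweepTrace(t, i, (0.0, 0.18), onset))
        peak = a1 + a2
        f = lambda x: a1 * np.exp(-x / tau1) + a2 * np.exp(-x / tau2) - peak / np.e
        expected = brentq(f, 0.0, 3.0)
        assert r.t_1e_s == pytest.approx(expected, abs=1e-4)

    def test_inward_current_sign_handled(self):
        r_neg = decay_time(exp_decay_trace(amp=-500.0))
        r_pos = decay_time(exp_decay_trace(amp=500.0))
        assert r_neg.peak_amplitude == pytest.approx(r_pos.peak_amplitude)
        assert r_neg.t_1e_s == pytest.approx(r_pos.t_1e_s)

    def test_no_peak_above_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 1.0, 1e-4)
        i = np.zeros_like(t)
        base = t <= 0.5
        i[base] = rng.normal(0, 5.0, base.sum())  # noisy baseline
        i[~base] = i[base].mean()  # flat pulse region: no response
        with pytest.raises(ValueError, match="peak"):
            decay_time(SweepTrace(t, i, (0.0, 0.4), 0.5))


class TestAverageSweeps:
    def test_mean_and_identity(self):
        r1 = decay_time(exp_decay_trace(tau=0.40))
        r2 = decay_time(exp_decay_trace(tau=0.38))
        avg = average_sweeps([r1, r2])
        assert avg.mean_t_1e_s == pytest.approx(0.39, abs=2e-4)
        single = average_sweeps([r1])
        assert single.mean_t_1e_s == r1.t_1e_s

    def test_uncrossed_excluded_with_count(self):
        crossed = decay_time(exp_decay_trace(tau=0.39))
        uncrossed = decay_time(exp_decay_trace(tau=50.0, pulse_s=1.0))
        avg = average_sweeps([crossed, uncrossed])
        assert avg.n_excluded == 1
        assert avg.mean_t_1e_s == pytest.approx(crossed.t_1e_s)
        none = average_sweeps([uncrossed])
        assert none.mean_t_1e_s is None


class TestDoseResponse:
    def test_normalization(self):
        dr = normalize_dose_response([(5.5, 800.0), (6.6, 400.0), (7.0, 40.0)])
        assert dict(dr.points)[5.5] == 1.0
        assert dict(dr.points)[6.6] == 0.5

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_dose_response([(6.6, 400.0)])

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_dose_response([(5.5, 0.0), (6.6, 1.0)])


class TestHillFit:
    PHS = (7.0, 6.9, 6.8, 6.7, 6.6, 6.5, 6.2, 5.5)

    def _points(self, pH05=6.6, n=-3.0, noise=0.0, rng=None):
        ys = hill_curve(np.array(self.PHS), pH05, n)
        if noise:
            ys = ys + rng.normal(0, noise, ys.shape)
        return DoseResponse(list(zip(self.PHS, ys)), 5.5)

    def test_noiseless_recovery(self):
        fit = fit_hill(self._points())
        assert fit.pH05 == pytest.approx(6.6, abs=1e-6)
        assert fit.hill_number == pytest.approx(3.0, abs=1e-6)

    def test_curve_at_midpoint_is_half(self):
        fit = fit_hill(self._points())
        assert float(fit.predict(fit.pH05)) == pytest.approx(0.5, abs=1e-9)

    def test_fitted_curve_bounded(self):
        rng = np.random.default_rng(11)
        fit = fit_hill(self._points(noise=0.02, rng=rng))
        grid = fit.predict(np.linspace(4.0, 9.0, 200))
        assert np.all(grid >= 0.0) and np.all(grid <= 1.0)

    def test_noisy_recovery_fixed_seed(self):
        rng = np.random.default_rng(1234)
        fit = fit_hill(self._points(noise=0.02, rng=rng))
        assert fit.pH05 == pytest.approx(6.6, abs=0.02)

    def test_shift_consistency(self):
        base = fit_hill(self._points())
        shifted_pts = DoseResponse(
            [(p + 0.25, y) for p, y in self._points().points], 5.75
        )
        shifted = fit_hill(shifted_pts)
        assert shifted.pH05 - base.pH05 == pytest.approx(0.25, abs=1e-6)

    def test_degenerate_data_rejected(self):
        flat = DoseResponse([(p, 0.5) for p in self.PHS], 5.5)
        with pytest.raises(ValueError, match="degenerate"):
            fit_hill(flat)
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill(DoseResponse([(5.5, 1.0), (6.0, 0.5), (6.5, 0.1)], 5.5))

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        pts = self._points(noise=0.02, rng=rng)
        f1, f2 = fit_hill(pts), fit_hill(pts)
        assert (f1.pH05, f1.n, f1.residual_sse) == (f2.pH05, f2.n, f2.residual_sse)


class TestWashOn:
    def test_constant_and_doubling(self):
        tc = washon_timecourse([100.0, 100.0, 100.0])
        assert np.allclose(tc.normalized_peaks, 1.0)
        tc2 = washon_timecourse([100.0, 120.0, 150.0, 180.0, 200.0])
        assert tc2.normalized_peaks[4] == pytest.approx(2.0)

    def test_saturating_washon_plateau(self):
        rng = np.random.default_rng(9)
        sweeps = np.arange(30)
        plateau = 2.3
        peaks = 100.0 * (1 + (plateau - 1) * (1 - np.exp(-sweeps / 4.0)))
        peaks = peaks * (1 + rng.normal(0, 0.01, peaks.shape))
        peaks[0] = 100.0
        tc = washon_timecourse(list(peaks))
        assert tc.normalized_peaks[-5:].mean() == pytest.approx(plateau, rel=0.05)

    def test_nonpositive_first_sweep(self):
        with pytest.raises(ValueError):
            washon_timecourse([0.0, 1.0])


class TestSweepIO:
    def test_csv_round_trip(self, tmp_path):
        trace = exp_decay_trace()
        trace.sweep_id, trace.pH = "s1", 5.5
        path = tmp_path / "sweep.csv"
        write_sweep_csv(path, trace)
        back = read_sweep_csv(path)
        np.testing.assert_allclose(back.current, trace.current)
        assert back.pulse_onset_s == trace.pulse_onset_s
        assert back.pH == 5.5
        assert decay_time(back).t_1e_s == pytest.approx(decay_time(trace).t_1e_s)
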