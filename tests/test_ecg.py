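"""Averaged-beat ECG chain: R detection, resting-cycle selection, beat
averaging, isoelectric line, landmark detection and QTpc identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratpheno.ecg import (
    AveragedBeat,
    RRSeries,
    analyze_ecg,
    average_beats,
    detect_landmarks,
    detect_r_peaks,
    estimate_isoelectric,
    qtpc,
    select_resting_cycles,
)
from ratpheno.errors import (
    ConfigurationError,
    DomainError,
    InsufficientCyclesError,
)
from ratpheno.synth import EcgParams, SynthesisRecipe, Wave, clean_cycle, gen_ecg
from ratpheno.traces import TraceSeries


def _rr_series(rr_ms):
    times = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    return RRSeries(r_times_s=times)


class TestDetectRPeaks:
    def test_all_peaks_recovered_zero_rr_sd(self, recipe):
        rec = recipe.with_(ecg=EcgParams(rr_sd_ms=0.0, noise_mv=0.0))
        trace, truth = gen_ecg(rec, notched=False, n_cycles=100)
        rr = detect_r_peaks(trace)
        assert rr.r_times_s.size == 100
        # within +/- 2 samples of ground truth
        tol = 2.0 / trace.sampling_rate_hz
        np.testing.assert_allclose(rr.r_times_s, truth["r_times_s"], atol=tol)

    def test_robust_to_5pct_white_noise(self, recipe):
        rec = recipe.with_(ecg=EcgParams(noise_mv=0.05))  # 5% of the 1 mV R peak
        trace, truth = gen_ecg(rec, notched=False, n_cycles=50)
        rr = detect_r_peaks(trace)
        assert rr.r_times_s.size == truth["r_times_s"].size
        np.testing.assert_allclose(rr.r_times_s, truth["r_times_s"], atol=2e-3)

    def test_flat_trace_rejected(self):
        trace = TraceSeries(1000.0, np.zeros(3000), "ecg_voltage", "mV")
        with pytest.raises(InsufficientCyclesError):
            detect_r_peaks(trace)


class TestSelectRestingCycles:
    def test_documented_example(self):
        # RR [150,160,140,154,200] ms: HRmin = 300 bpm (RR 200); band top
        # 330 bpm; next-slowest HR is 375 -> only the RR=200 cycle selected
        rr = _rr_series([150.0, 160.0, 140.0, 154.0, 200.0])
        mask = select_resting_cycles(rr, 0.10)
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_all_equal_all_selected(self):
        mask = select_resting_cycles(_rr_series([150.0] * 6))
        assert mask.all()

    def test_zero_band_selects_argmax_rr(self):
        # dyadic RR values so the repeated intervals are bit-identical
        rr = _rr_series([128.0, 256.0, 128.0, 256.0])
        mask = select_resting_cycles(rr, 0.0)
        np.testing.assert_array_equal(mask, [False, True, False, True])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=80.0, max_value=400.0), min_size=2, max_size=40)
    )
    def test_equals_brute_force_rule(self, rr_ms):
        """Selection mask must match an element-wise HR <= 1.1*HRmin filter."""
        rr = _rr_series(rr_ms)
        mask = select_resting_cycles(rr, 0.10)
        hr = 60000.0 / np.asarray(rr_ms)
        brute = np.array([h <= 1.1 * hr.min() for h in hr])
        np.testing.assert_array_equal(mask, brute)
        assert mask[int(np.argmin(hr))]  # lowest-rate cycle always in


class TestAverageBeats:
    def _trace_from_cycles(self, cycle, n, rr_samples, fs=1000.0):
        gap = np.zeros(rr_samples - cycle.size)
        v = np.concatenate([np.concatenate([cycle, gap]) for _ in range(n)])
        return TraceSeries(fs, v, "ecg_voltage", "mV")

    def test_mean_of_identical_cycles_is_the_cycle(self, recipe):
        rec = recipe.with_(ecg=EcgParams(rr_sd_ms=0.0, noise_mv=0.0))
        trace, _ = gen_ecg(rec, notched=False, n_cycles=20)
        rr = detect_r_peaks(trace)
        mask = np.ones(rr.n_cycles, dtype=bool)
        beat = average_beats(trace, rr, mask)
        # every used cycle equals the average to near machine precision
        c = np.round(rr.r_times_s[5] * trace.sampling_rate_hz).astype(int)
        n_pre = int(round(60.0 * trace.sampling_rate_hz / 1000.0))
        n_post = int(round(110.0 * trace.sampling_rate_hz / 1000.0))
        single = trace.values[c - n_pre : c + n_post + 1]
        np.testing.assert_allclose(beat.waveform_mv, single, atol=1e-12)

    def test_averaging_linearity(self, recipe):
        rec = recipe.with_(ecg=EcgParams(rr_sd_ms=0.0, noise_mv=0.0))
        trace, _ = gen_ecg(rec, notched=True, n_cycles=10)
        rr = detect_r_peaks(trace)
        mask = np.ones(rr.n_cycles, dtype=bool)
        b1 = average_beats(trace, rr, mask)
        scaled = TraceSeries(trace.sampling_rate_hz, 3.0 * trace.values, "ecg_voltage", "mV")
        b3 = average_beats(scaled, rr, mask)
        np.testing.assert_allclose(b3.waveform_mv, 3.0 * b1.waveform_mv, rtol=1e-12)

    def test_opposite_cycles_average_to_zero(self):
        # cycles +v and -v at every sample must cancel exactly
        fs = 1000.0
        cycle = np.sin(np.linspace(0, 2 * np.pi, 100))
        v = np.zeros(1400)
        v[100:200] = cycle
        v[400:500] = -cycle
        v[700:800] = cycle
        v[1000:1100] = -cycle
        trace = TraceSeries(fs, v, "ecg_voltage", "mV")
        rr = RRSeries(np.array([0.125, 0.425, 0.725, 1.025]))
        beat = average_beats(
            trace, rr, np.array([False, True, True]), window_ms=(20, 50)
        )
        np.testing.assert_allclose(beat.waveform_mv, 0.0, atol=1e-12)

    def test_notched_t_survives_averaging(self, recipe):
        trace, _ = gen_ecg(recipe, notched=True, n_cycles=40)
        feats = analyze_ecg(trace)
        assert feats.notched_t

    def test_no_selected_cycles_error(self, recipe):
        trace, _ = gen_ecg(recipe, notched=False, n_cycles=10)
        rr = detect_r_peaks(trace)
        with pytest.raises(InsufficientCyclesError):
            average_beats(trace, rr, np.zeros(rr.n_cycles, dtype=bool))


class TestIsoelectric:
    def test_baseline_offset_recovered(self, recipe):
        rec = recipe.with_(ecg=EcgParams(baseline_mv=0.1))
        trace, _ = gen_ecg(rec, notched=False, n_cycles=60)
        rr = detect_r_peaks(trace)
        beat = average_beats(trace, rr, select_resting_cycles(rr))
        iso = estimate_isoelectric(beat)
        assert iso.value_mv == pytest.approx(0.1, abs=0.002)

    def test_zero_offset(self, recipe):
        trace, _ = gen_ecg(recipe, notched=False, n_cycles=60)
        rr = detect_r_peaks(trace)
        beat = average_beats(trace, rr, select_resting_cycles(rr))
        assert estimate_isoelectric(beat).value_mv == pytest.approx(0.0, abs=0.002)

    def test_constant_waveform_baseline_exact(self):
        beat = AveragedBeat(1000.0, 60.0, 110.0, np.full(171, 0.42), 5)
        assert estimate_isoelectric(beat).value_mv == pytest.approx(0.42, abs=1e-15)

    def test_window_outside_beat_rejected(self, recipe):
        trace, _ = gen_ecg(recipe, notched=False, n_cycles=10)
        rr = detect_r_peaks(trace)
        beat = average_beats(trace, rr, select_resting_cycles(rr))
        with pytest.raises(ConfigurationError):
            estimate_isoelectric(beat, tp_window_ms=(-100.0, -80.0))


class TestLandmarks:
    def _beat(self, recipe, notched, n_cycles=60):
        trace, truth = gen_ecg(recipe, notched=notched, n_cycles=n_cycles)
        rr = detect_r_peaks(trace)
        beat = average_beats(trace, rr, select_resting_cycles(rr))
        iso = estimate_isoelectric(beat)
        return detect_landmarks(beat, iso), truth

    def test_smooth_beat_landmarks(self, recipe):
        lm, truth = self._beat(recipe, notched=False)
        assert not lm["notched_t"]
        assert lm["q_onset_ms"] == pytest.approx(truth["q_onset_ms"], abs=2.0)
        assert lm["t_peak_ms"] == pytest.approx(truth["t_peak_ms"], abs=2.0)

    def test_notched_beat_landmarks(self, recipe):
        lm, truth = self._beat(recipe, notched=True)
        assert lm["notched_t"]
        assert lm["t_peak_ms"] == pytest.approx(truth["t_peak_ms"], abs=2.0)

    def test_equal_bumps_tie_breaks_to_earlier(self):
        # symmetric double-T beat built directly: argmax must take the first
        params = EcgParams(notch_amp_ratio=1.0, rr_sd_ms=0.0, noise_mv=0.0)
        fs = 2000.0
        t_ms = np.arange(-60.0, 110.0, 1000.0 / fs)
        v = clean_cycle(t_ms, params, notched=True)
        beat = AveragedBeat(fs, 60.0, 110.0, v, 1)
        lm = detect_landmarks(beat, 0.0)
        assert lm["notched_t"]
        assert lm["t_peak_ms"] < params.t.center_ms  # earlier bump wins

    def test_j_point_before_t_peak_when_notched(self, recipe):
        lm, _ = self._beat(recipe, notched=True)
        assert lm["s_end_or_j_ms"] < lm["t_peak_ms"]
        assert lm["s_end_or_j_ms"] > 0


class TestQTpc:
    def test_fixed_point_rr_equals_f(self):
        assert qtpc(50.0, 140.0, 140.0) == pytest.approx(50.0)

    def test_quarter_rr_doubles(self):
        assert qtpc(50.0, 35.0, 140.0) == pytest.approx(100.0)

    def test_joint_rescale_invariance(self):
        base = qtpc(47.0, 150.0, 140.0)
        for c in (0.25, 2.0, 13.7):
            assert qtpc(47.0, 150.0 * c, 140.0 * c) == pytest.approx(base, rel=1e-12)

    def test_sqrt_rr_scaling_makes_qtpc_constant(self):
        """If QTpeak is generated proportional to sqrt(RR), QTpc is flat
        across RR levels (f fixed)."""
        f = 140.0
        k = 50.0 / np.sqrt(f)
        vals = [qtpc(k * np.sqrt(rr), rr, f) for rr in (100.0, 140.0, 200.0)]
        assert np.ptp(vals) / np.mean(vals) < 0.01

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            qtpc(0.0, 140.0, 140.0)
        with pytest.raises(DomainError):
            qtpc(50.0, -1.0, 140.0)


class TestAnalyzeEcg:
    def test_zero_rr_sd_collapses_qtpc_to_qtpeak(self, recipe):
        rec = recipe.with_(ecg=EcgParams(rr_sd_ms=0.0))
        feats = analyze_ecg(gen_ecg(rec, notched=False, n_cycles=40)[0])
        assert feats.rr_selected_mean_ms == pytest.approx(feats.f_individual_ms)
        assert feats.qtpc_ms == pytest.approx(feats.qt_peak_ms)

    def test_wt_like_vs_dmd_like_contrast(self, recipe):
        """Notched-T beats with a later T peak must raise QTpc relative to a
        smooth-T run under matched RR parameters."""
        wt = analyze_ecg(gen_ecg(recipe, notched=False, n_cycles=60)[0])
        dmd_ecg = EcgParams(t=Wave(0.20, 55.0, 10.0))
        dmd = analyze_ecg(
            gen_ecg(recipe.with_(ecg=dmd_ecg), notched=True, n_cycles=60)[0]
        )
        assert not wt.notched_t
        assert dmd.notched_t
        assert dmd.qtpc_ms > wt.qtpc_ms

    def test_qtpc_close_to_qtpeak_at_small_rr_spread(self, recipe):
        trace, _ = gen_ecg(recipe, notched=False, n_cycles=60)
        feats = analyze_ecg(trace)
        assert feats.qtpc_ms == pytest.approx(feats.qt_peak_ms, rel=0.05)
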