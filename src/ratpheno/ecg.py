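"""Averaged-beat ECG analysis for telemetric rat recordings.

The analysis chain mirrors how resting telemetric ECG is read in dystrophic
rat models:

1.  R peaks are detected (derivative-free prominence detector with a 50 ms
    refractory period) and RR intervals / instantaneous heart rate derived.
2.  Resting cycles are selected: every cycle whose instantaneous heart rate
    lies between the lowest observed rate and 10% above it.  This excludes
    stress-driven sympathetic acceleration.
3.  Selected cycles are aligned on the R peak and averaged pointwise over a
    fixed window (default -60 to +110 ms).
4.  The isoelectric line is the mean voltage of the TP segment (the quiet
    stretch after T and before the next P; in the averaged window this is
    the earliest pre-P slice).
5.  Landmarks: Q onset (first departure from baseline beyond 5% of the R
    amplitude within the QRS search window), T peak (largest deviation from
    baseline in the T window), and the end of the QRS — the first
    baseline crossing after S, or, for a notched T wave where the trace may
    never return to baseline, the J point located as the first sustained
    "return to horizontal" of the smoothed derivative.
6.  QTpeak = T peak - Q onset, rate-corrected by the modified Bazett
    formula  QTpc = QTpeak / sqrt(RR / f)  with RR the mean interval of the
    selected resting cycles and f the rat's own mean RR over the whole
    recording (so QTpc is invariant to jointly rescaling RR and f).

A notched T wave (two T maxima separated by a dip that stays above the
baseline) is the dystrophic signature; classification is part of the
landmark pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientCyclesError,
    LandmarkFailureError,
)
from .traces import ECG_VOLTAGE, TraceSeries

DEFAULT_BAND_FRACTION = 0.10
DEFAULT_WINDOW_MS = (60.0, 110.0)  # (pre-R, post-R)
DEFAULT_TP_WINDOW_MS = (-60.0, -45.0)
REFRACTORY_MS = 50.0


@dataclass(frozen=True)
class RRSeries:
    """R-peak times (s) with derived RR intervals (ms) and heart rate."""

    r_times_s: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.r_times_s, dtype=float)
        if rt.size < 3:
            raise InsufficientCyclesError(f"need >= 3 R peaks, got {rt.size}")
        if np.any(np.diff(rt) <= 0):
            raise InsufficientCyclesError("R times must be strictly increasing")
        object.__setattr__(self, "r_times_s", rt)

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.r_times_s) * 1000.0

    @property
    def hr_bpm(self) -> np.ndarray:
        return 60000.0 / self.rr_ms

    @property
    def n_cycles(self) -> int:
        return self.rr_ms.size


@dataclass(frozen=True)
class AveragedBeat:
    """Mean resting cardiac cycle, sampled on a fixed window around R."""

    sampling_rate_hz: float
    pre_ms: float
    post_ms: float
    waveform_mv: np.ndarray
    n_cycles_used: int

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the R peak."""
        n_pre = int(round(self.pre_ms * self.sampling_rate_hz / 1000.0))
        return (np.arange(self.waveform_mv.size) - n_pre) / self.sampling_rate_hz * 1000.0


@dataclass(frozen=True)
class IsoelectricEstimate:
    value_mv: float
    window_ms: tuple[float, float]
    noise_sd_mv: float


@dataclass(frozen=True)
class LandmarkParams:
    onset_threshold_frac: float = 0.05   # of R amplitude
    qrs_search_pre_ms: float = 20.0
    t_search_ms: tuple[float, float] = (15.0, 90.0)
    notch_depth_frac: float = 0.05       # minimal dip depth, fraction of T amp
    notch_height_frac: float = 0.30      # minimal bump height, fraction of T amp
    notch_min_separation_ms: float = 4.0  # minimal spacing of the two T bumps
    t_smooth_ms: float = 1.5             # pre-smoothing of the T window
    j_eps_frac_per_ms: float = 0.02      # "horizontal" slope band, R amp per ms
    j_run_ms: float = 3.0                # how long the slope must stay in band


@dataclass(frozen=True)
class ECGFeatures:
    baseline_mv: float
    q_onset_ms: float
    s_end_or_j_ms: float
    t_peak_ms: float
    qt_peak_ms: float
    notched_t: bool
    rr_selected_mean_ms: float
    f_individual_ms: float
    qtpc_ms: float
    n_cycles: int
    n_selected: int
    n_averaged: int


# --------------------------------------------------------------------------


def detect_r_peaks(
    trace: TraceSeries,
    refractory_ms: float = REFRACTORY_MS,
    height_frac: float = 0.5,
) -> RRSeries:
    """Locate R peaks as prominent maxima above ``height_frac`` of the
    largest deviation from the median level, at least one refractory period
    apart."""
    if trace.signal_kind != ECG_VOLTAGE:
        raise ConfigurationError("detect_r_peaks expects an ecg_voltage trace")
    v = trace.values - np.median(trace.values)
    top = float(np.max(v))
    if top <= 0 or np.ptp(trace.values) == 0:
        raise InsufficientCyclesError("flat trace: no R peaks")
    distance = max(1, int(round(refractory_ms / 1000.0 * trace.sampling_rate_hz)))
    idx, _ = find_peaks(v, height=height_frac * top, distance=distance)
    if idx.size < 3:
        raise InsufficientCyclesError(f"found only {idx.size} R peaks (need >= 3)")
    return RRSeries(r_times_s=idx / trace.sampling_rate_hz)


def select_resting_cycles(
    rr: RRSeries, band_fraction: float = DEFAULT_BAND_FRACTION
) -> np.ndarray:
    """Boolean mask over cycles: selected iff the instantaneous heart rate
    is within ``band_fraction`` above the lowest rate of the recording.

    Equivalent to RR >= RRmax / (1 + band_fraction).  The lowest-rate cycle
    is always selected.
    """
    if band_fraction < 0:
        raise ConfigurationError("band_fraction must be >= 0")
    hr = rr.hr_bpm
    return hr <= hr.min() * (1.0 + band_fraction)


def average_beats(
    trace: TraceSeries,
    rr: RRSeries,
    mask: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> AveragedBeat:
    """Align selected cycles on their R peak and average pointwise.

    Cycle i is anchored at R peak i; a cycle is dropped (and counted) when
    its window would overrun the trace bounds or reach into a neighbouring
    R peak.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rr.n_cycles,):
        raise ConfigurationError("mask must have one entry per RR interval")
    if not mask.any():
        raise InsufficientCyclesError("no cycles selected")
    pre_ms, post_ms = window_ms
    fs = trace.sampling_rate_hz
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    r_idx = np.round(rr.r_times_s * fs).astype(int)
    segments = []
    for i in np.nonzero(mask)[0]:
        c = r_idx[i]
        if i == 0:
            continue  # no preceding beat: the pre-R window is unrepresentative
        if c - n_pre < 0 or c + n_post >= trace.n_samples:
            continue
        if (c - r_idx[i - 1]) * 1000.0 / fs < pre_ms:
            continue
        if (r_idx[i + 1] - c) * 1000.0 / fs < post_ms:
            continue
        segments.append(trace.values[c - n_pre : c + n_post + 1])
    if not segments:
        raise InsufficientCyclesError("no selected cycle fits the averaging window")
    return AveragedBeat(
        sampling_rate_hz=fs,
        pre_ms=pre_ms,
        post_ms=post_ms,
        waveform_mv=np.mean(segments, axis=0),
        n_cycles_used=len(segments),
    )


def estimate_isoelectric(
    beat: AveragedBeat, tp_window_ms: tuple[float, float] = DEFAULT_TP_WINDOW_MS
) -> IsoelectricEstimate:
    """Baseline voltage as the mean over the TP segment of the averaged beat.

    The default window is the earliest 15 ms of the beat window, which for a
    (-60, +110) ms window at rat heart rates sits after the previous T and
    before the P wave.
    """
    t = beat.times_ms
    lo, hi = tp_window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ConfigurationError(
            f"TP window {tp_window_ms} outside beat window ({t[0]:.0f}, {t[-1]:.0f}) ms"
        )
    sel = (t >= lo) & (t <= hi)
    seg = beat.waveform_mv[sel]
    return IsoelectricEstimate(
        value_mv=float(np.mean(seg)),
        window_ms=(lo, hi),
        noise_sd_mv=float(np.std(seg)),
    )


def detect_landmarks(
    beat: AveragedBeat,
    baseline: IsoelectricEstimate | float,
    params: LandmarkParams = LandmarkParams(),
) -> dict:
    """Locate Q onset, the end of the QRS (S end or J point), the T peak and
    the notched-T flag on an averaged beat.

    Returns a dict with keys ``q_onset_ms``, ``s_end_or_j_ms``,
    ``t_peak_ms``, ``qt_peak_ms``, ``notched_t``, ``n_t_maxima``.
    """
    if isinstance(baseline, IsoelectricEstimate):
        b = baseline.value_mv
        noise_sd = baseline.noise_sd_mv
    else:
        b = float(baseline)
        noise_sd = 0.0
    t = beat.times_ms
    dev = beat.waveform_mv - b
    r_i = int(np.argmin(np.abs(t)))
    r_amp = float(dev[r_i])
    if r_amp <= 0:
        raise LandmarkFailureError("non-positive R amplitude relative to baseline")
    thr = params.onset_threshold_frac * r_amp

    # Q onset: first departure beyond threshold inside the QRS search window
    pre = (t >= -params.qrs_search_pre_ms) & (t <= 0)
    hits = np.nonzero(np.abs(dev[pre]) > thr)[0]
    if hits.size == 0:
        raise LandmarkFailureError("no QRS departure from baseline found")
    q_onset = float(t[pre][hits[0]])

    # T window
    lo, hi = params.t_search_ms
    twin = (t >= lo) & (t <= hi)
    tdev = dev[twin]
    ttimes = t[twin]
    t_amp = float(np.max(np.abs(tdev)))
    if t_amp <= 2.0 * noise_sd:
        raise LandmarkFailureError("no T deflection above twice the baseline noise")
    # light smoothing so residual averaging noise cannot fake a second bump
    ks = max(1, int(round(params.t_smooth_ms * beat.sampling_rate_hz / 1000.0)))
    tsm = np.convolve(tdev, np.ones(ks) / ks, mode="same") if ks > 1 else tdev
    sep = max(1, int(round(params.notch_min_separation_ms * beat.sampling_rate_hz / 1000.0)))
    peaks, _ = find_peaks(
        tsm,
        height=params.notch_height_frac * t_amp,
        prominence=params.notch_depth_frac * t_amp,
        distance=sep,
    )
    notched = peaks.size >= 2
    if notched:
        # dip between the two tallest bumps must stay above baseline
        top2 = peaks[np.argsort(tsm[peaks])[::-1][:2]]
        a, c = int(np.min(top2)), int(np.max(top2))
        dip = float(np.min(tsm[a : c + 1]))
        notched = dip > 0
    if peaks.size >= 1:
        heights = tsm[peaks]
        # tie-break: earlier maximum wins (argmax takes the first of equals)
        t_peak = float(ttimes[peaks[int(np.argmax(heights))]])
    else:
        t_peak = float(ttimes[int(np.argmax(np.abs(tdev)))])

    # end of QRS
    s_region = (t > 0) & (t <= lo)
    s_rel = np.nonzero(s_region)[0]
    s_trough = s_rel[int(np.argmin(dev[s_region]))]
    if not notched:
        after = np.nonzero((np.arange(t.size) > s_trough) & (t <= hi))[0]
        cross = after[np.nonzero(dev[after] >= 0)[0]]
        if cross.size == 0:
            raise LandmarkFailureError("trace never recrosses the isoelectric line after S")
        s_end = float(t[cross[0]])
    else:
        dt_ms = 1000.0 / beat.sampling_rate_hz
        deriv = np.gradient(dev, dt_ms)  # mV per ms
        k = max(1, int(round(1.0 / dt_ms)))
        kernel = np.ones(k) / k
        deriv = np.convolve(deriv, kernel, mode="same")
        eps = params.j_eps_frac_per_ms * r_amp
        run = max(1, int(round(params.j_run_ms / dt_ms)))
        flat = np.abs(deriv) < eps
        s_end = None
        for i in range(s_trough + 1, t.size - run):
            if flat[i : i + run].all():
                s_end = float(t[i])
                break
        if s_end is None:
            raise LandmarkFailureError("no return to horizontal found after S (J point)")

    return {
        "q_onset_ms": q_onset,
        "s_end_or_j_ms": s_end,
        "t_peak_ms": t_peak,
        "qt_peak_ms": t_peak - q_onset,
        "notched_t": bool(notched),
        "n_t_maxima": int(peaks.size),
    }


def qtpc(qt_peak_ms: float, rr_selected_mean_ms: float, f_individual_ms: float) -> float:
    """Modified Bazett correction: QTpc = QTpeak / sqrt(RR / f).

    ``RR`` is the mean interval over the selected resting cycles and ``f``
    the rat's mean RR over the whole recording; equal values leave QTpeak
    unchanged, and jointly rescaling both leaves QTpc unchanged.
    """
    if qt_peak_ms <= 0 or rr_selected_mean_ms <= 0 or f_individual_ms <= 0:
        raise DomainError("qtpc inputs must all be > 0")
    return qt_peak_ms / np.sqrt(rr_selected_mean_ms / f_individual_ms)


def analyze_ecg(
    trace: TraceSeries,
    band_fraction: float = DEFAULT_BAND_FRACTION,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    tp_window_ms: tuple[float, float] = DEFAULT_TP_WINDOW_MS,
    landmark_params: LandmarkParams = LandmarkParams(),
) -> ECGFeatures:
    """Full averaged-beat analysis of one ECG trace."""
    rr = detect_r_peaks(trace)
    mask = select_resting_cycles(rr, band_fraction)
    beat = average_beats(trace, rr, mask, window_ms)
    iso = estimate_isoelectric(beat, tp_window_ms)
    lm = detect_landmarks(beat, iso, landmark_params)
    rr_sel = float(np.mean(rr.rr_ms[mask]))
    f_ind = float(np.mean(rr.rr_ms))
    return ECGFeatures(
        baseline_mv=iso.value_mv,
        q_onset_ms=lm["q_onset_ms"],
        s_end_or_j_ms=lm["s_end_or_j_ms"],
        t_peak_ms=lm["t_peak_ms"],
        qt_peak_ms=lm["qt_peak_ms"],
        notched_t=lm["notched_t"],
        rr_selected_mean_ms=rr_sel,
        f_individual_ms=f_ind,
        qtpc_ms=qtpc(lm["qt_peak_ms"], rr_sel, f_ind),
        n_cycles=rr.n_cycles,
        n_selected=int(mask.sum()),
        n_averaged=beat.n_cycles_used,
    )
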