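"""Functional muscle and ventilatory indices.

Grip test: five repetitions; maximal force is the maximum over the five,
and the force maintenance index (FMI) is the mean of the last three trials
as a percentage of the maximum — a scale-free fatigue-resistance index.

In vivo stimulation: the force-frequency relationship over the ten standard
stimulation frequencies (10..140 Hz); maximal tetanic force is the plateau,
read deterministically as the curve maximum; specific force divides by the
muscle mass; f50 (frequency at half-maximal relative force, linearly
interpolated) summarizes the right-shift of the curve; the fatigue FMI is
the 20th tetanic contraction as a percentage of the series maximum.

Whole-body plethysmography (box-flow convention: inspiration is the
negative phase): PIF/PEF are the maximal negative/positive recorded values,
inspiration time is the mean duration of the negative phases, and tidal
volume is the mean per-breath integral of inspiratory flow magnitude
(trapezoid rule with sub-sample boundary interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, NoBreathError, TraceShapeError
from .traces import BOX_FLOW, TraceSeries, TrialSeries

N_GRIP_TRIALS = 5
N_FATIGUE_CONTRACTIONS = 20


@dataclass(frozen=True)
class GripMetrics:
    max_force_mn: float
    fmi_percent: float


@dataclass(frozen=True)
class StimMetrics:
    max_tetanic_force_mn: float
    specific_force_mn_per_g: float
    f50_hz: float
    fatigue_fmi_percent: float
    relative_ff_percent: np.ndarray  # % of max at each stimulation frequency
    frequencies_hz: np.ndarray


@dataclass(frozen=True)
class BreathMetrics:
    pif_ml_s: float
    pef_ml_s: float
    ti_s: float
    tidal_volume_ml: float
    respiratory_rate_bpm: float
    n_breaths: int


def grip_metrics(trials: TrialSeries) -> GripMetrics:
    """Maximal grip force and force maintenance index from 5 repetitions."""
    if trials.trial_kind != "grip":
        raise TraceShapeError("grip_metrics expects a grip TrialSeries")
    f = trials.force_mn
    if f.size != N_GRIP_TRIALS:
        raise TraceShapeError(f"grip test needs exactly {N_GRIP_TRIALS} trials, got {f.size}")
    fmax = float(np.max(f))
    if fmax == 0:
        raise DegenerateInputError("all grip forces are zero")
    return GripMetrics(
        max_force_mn=fmax,
        fmi_percent=float(np.mean(f[-3:]) / fmax * 100.0),
    )


def stim_metrics(
    ff: TrialSeries, fatigue: TrialSeries, muscle_mass_g: float
) -> StimMetrics:
    """Force-frequency and fatigue indices for one stimulated muscle."""
    if ff.trial_kind != "force_frequency" or fatigue.trial_kind != "fatigue":
        raise TraceShapeError("stim_metrics expects force_frequency and fatigue series")
    if fatigue.force_mn.size != N_FATIGUE_CONTRACTIONS:
        raise TraceShapeError(
            f"fatigue series needs {N_FATIGUE_CONTRACTIONS} contractions, "
            f"got {fatigue.force_mn.size}"
        )
    if not muscle_mass_g > 0:
        raise DegenerateInputError("muscle mass must be > 0")
    fmax = float(np.max(ff.force_mn))
    if fmax == 0:
        raise DegenerateInputError("all stimulation forces are zero")
    rel = ff.force_mn / fmax * 100.0
    # f50: first crossing of 50% of max, linearly interpolated
    above = np.nonzero(rel >= 50.0)[0]
    if above.size == 0:
        raise DegenerateInputError("relative force never reaches 50% of max")
    i = int(above[0])
    if i == 0:
        f50 = float(ff.x[0])
    else:
        x0, x1 = ff.x[i - 1], ff.x[i]
        y0, y1 = rel[i - 1], rel[i]
        f50 = float(x0 + (50.0 - y0) / (y1 - y0) * (x1 - x0))
    fat_max = float(np.max(fatigue.force_mn))
    if fat_max == 0:
        raise DegenerateInputError("all fatigue contractions are zero")
    return StimMetrics(
        max_tetanic_force_mn=fmax,
        specific_force_mn_per_g=fmax / muscle_mass_g,
        f50_hz=f50,
        fatigue_fmi_percent=float(fatigue.force_mn[-1] / fat_max * 100.0),
        relative_ff_percent=rel,
        frequencies_hz=ff.x.copy(),
    )


# --------------------------------------------------------------------------
# plethysmography


def _inspiration_phases(
    flow: np.ndarray, fs: float, smooth_ms: float, min_breath_ms: float
) -> list[tuple[float, float]]:
    """Negative-phase boundaries (fractional sample indices).

    Phases are found on a moving-average-smoothed copy (guard against
    noise-induced zero-crossings) and boundaries refined to sub-sample zero
    crossings of the raw trace.  Phases touching the trace edges or shorter
    than ``min_breath_ms`` are discarded.
    """
    k = max(1, int(round(smooth_ms / 1000.0 * fs)))
    smoothed = np.convolve(flow, np.ones(k) / k, mode="same") if k > 1 else flow
    neg = smoothed < 0
    # runs of negative samples
    edges = np.diff(neg.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if neg[0]:
        starts = np.concatenate([[0], starts])
    if neg[-1]:
        ends = np.concatenate([ends, [flow.size]])
    phases = []
    for s, e in zip(starts, ends):
        if s == 0 or e == flow.size:
            continue  # incomplete breath at the trace edge
        if (e - s) / fs * 1000.0 < min_breath_ms:
            continue
        # refine to raw sign changes within the smoothing neighbourhood
        while s > 0 and flow[s - 1] < 0:
            s -= 1
        while s < e and flow[s] >= 0:
            s += 1
        while e < flow.size and flow[e] < 0:
            e += 1
        while e > s and flow[e - 1] >= 0:
            e -= 1
        if e - s < 2 or s == 0 or e == flow.size:
            continue
        # sub-sample crossings: flow[s-1] >= 0 > flow[s], flow[e-1] < 0 <= flow[e]
        f0, f1 = flow[s - 1], flow[s]
        start = (s - 1) + (f0 / (f0 - f1) if f0 > 0 else 1.0)
        g0, g1 = flow[e - 1], flow[e]
        end = (e - 1) + (g0 / (g0 - g1) if g1 > 0 else 1.0)
        phases.append((float(start), float(end)))
    return phases


def _phase_volume(flow: np.ndarray, start: float, end: float, dt: float) -> float:
    """Trapezoid integral of |flow| between fractional boundaries where the
    flow crosses zero (boundary values are 0 by construction)."""
    i0 = int(np.ceil(start))
    i1 = int(np.floor(end))
    mag = np.abs(flow[i0 : i1 + 1])
    vol = float(np.trapezoid(mag, dx=dt)) if i1 > i0 else 0.0
    # boundary slivers: linear from 0 at the crossing to the first/last sample
    vol += 0.5 * float(np.abs(flow[i0])) * (i0 - start) * dt
    vol += 0.5 * float(np.abs(flow[i1])) * (end - i1) * dt
    return vol


def breath_metrics(
    flow: TraceSeries,
    smooth_ms: float = 25.0,
    min_breath_ms: float = 50.0,
    invert: bool = False,
) -> BreathMetrics:
    """Breath-cycle metrics from a box-flow trace.

    ``invert=True`` negates the trace at load for recordings made with the
    opposite flow convention.
    """
    if flow.signal_kind != BOX_FLOW:
        raise TraceShapeError("breath_metrics expects a box_flow trace")
    v = -flow.values if invert else flow.values
    fs = flow.sampling_rate_hz
    if not np.any(v < 0):
        raise NoBreathError("no negative flow: trace contains no inspiration phase")
    phases = _inspiration_phases(v, fs, smooth_ms, min_breath_ms)
    if not phases:
        raise NoBreathError("no complete inspiration phase found")
    dt = 1.0 / fs
    durations = [(e - s) * dt for s, e in phases]
    volumes = [_phase_volume(v, s, e, dt) for s, e in phases]
    return BreathMetrics(
        pif_ml_s=float(np.max(-v)),
        pef_ml_s=float(np.max(v)) if np.any(v > 0) else 0.0,
        ti_s=float(np.mean(durations)),
        tidal_volume_ml=float(np.mean(volumes)),
        respiratory_rate_bpm=len(phases) / flow.duration_s * 60.0,
        n_breaths=len(phases),
    )
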