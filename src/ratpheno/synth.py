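"""Synthetic cohort generator.

Builds rats, physiological traces and trial series with exactly the
statistical structure the downstream analyses assume, together with ground
-truth tables, so that every stage of the pipeline can be verified without
animal data.

The generative laws are:

* organ mass  ``m = slope * (TL^3 - x_intercept) * atrophy * (1 + eps)`` —
  linear in cubic tibia length (mass scales with a volume, not a length),
  with a genotype-specific atrophy multiplier and multiplicative noise;
* body mass = muscle-linked part (same TL^3 law, atrophied in DMD) plus a
  non-muscle constant with its own coefficient of variation (adiposity and
  viscera vary independently of bone growth).  This independent variance is
  what makes body mass an imperfect growth corrector in the synthetic world;
* ECG cycles are sums of Gaussian bumps for P, Q, R, S, T at fixed offsets
  from the R peak; a notched T is a pair of bumps whose midpoint dip stays
  above baseline; RR intervals are Gaussian;
* breath flow is a negative half-sine inspiration (closed-form tidal volume
  ``2*A*Ti/pi``) followed by a positive expiratory lobe of equal area;
* grip/fatigue series decay geometrically; the force-frequency curve is a
  logistic sigmoid in stimulation frequency.

Defaults are scaled to adult male Sprague Dawley rats (~40 mm tibia, ~500 g,
resting heart rate ~430 bpm, ~100 breaths/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GenerationError
from .records import AnimalRecord
from .traces import BOX_FLOW, ECG_VOLTAGE, TraceSeries, TrialSeries

# --------------------------------------------------------------------------
# recipe dataclasses


@dataclass(frozen=True)
class Allometry:
    """Linear mass-vs-TL^3 law for one organ."""

    slope_g_per_mm3: float
    x_intercept_mm3: float
    atrophy_dmd: float = 1.0  # multiplicative, in (0, 1]

    def __post_init__(self) -> None:
        if not self.slope_g_per_mm3 > 0:
            raise GenerationError("allometry slope must be > 0")
        if not 0 < self.atrophy_dmd <= 1:
            raise GenerationError("atrophy factor must be in (0, 1]")


@dataclass(frozen=True)
class Wave:
    """One Gaussian ECG wave: amplitude (mV), center and width (ms, R=0)."""

    amp_mv: float
    center_ms: float
    sigma_ms: float


@dataclass(frozen=True)
class EcgParams:
    rr_mean_ms: float = 140.0
    rr_sd_ms: float = 5.0
    p: Wave = Wave(0.07, -34.0, 4.0)
    q: Wave = Wave(-0.10, -8.0, 2.0)
    r: Wave = Wave(1.00, 0.0, 3.0)
    s: Wave = Wave(-0.25, 6.0, 3.0)
    t: Wave = Wave(0.20, 45.0, 10.0)
    notch_offset_ms: float = 12.0   # separation of the two T bumps
    notch_depth: float = 0.20       # second-bump prominence / T peak amplitude
    notch_amp_ratio: float = 0.85   # second bump amplitude / first
    baseline_mv: float = 0.0
    noise_mv: float = 0.01
    sampling_rate_hz: float = 2000.0


@dataclass(frozen=True)
class BreathParams:
    amp_ml_s: float = 2.0          # inspiratory half-sine amplitude A
    ti_s: float = 0.2              # inspiration time Ti
    rate_bpm: float = 100.0        # breaths per minute
    exp_fraction: float = 0.6      # active-exhale fraction of the remainder
    noise_ml_s: float = 0.0
    sampling_rate_hz: float = 1000.0


@dataclass(frozen=True)
class TrialParams:
    grip_max_mn: float = 15000.0
    grip_decay: float = 0.95
    fatigue_decay: float = 0.97
    ff_fmax_mn: float = 2500.0
    ff_f50_hz: float = 40.0
    ff_slope_hz: float = 8.0
    frequencies_hz: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 80, 100, 120, 140)
    n_grip: int = 5
    n_fatigue: int = 20
    noise_cv: float = 0.05
    # DMD modifiers
    dmd_force_factor: float = 0.6
    dmd_f50_shift_hz: float = 15.0
    dmd_grip_decay: float = 0.90
    dmd_fatigue_decay: float = 0.93


def default_allometry() -> dict[str, Allometry]:
    return {
        "ta": Allometry(2.0e-5, 14000.0, atrophy_dmd=0.70),
        "edl": Allometry(3.5e-6, 14000.0, atrophy_dmd=0.70),
        "soleus": Allometry(3.6e-6, 14000.0, atrophy_dmd=0.80),
        "heart": Allometry(2.6e-5, 14000.0, atrophy_dmd=0.85),
        "testis": Allometry(3.6e-5, 14000.0, atrophy_dmd=1.00),
    }


@dataclass(frozen=True)
class SynthesisRecipe:
    """Full parameterization of a synthetic study."""

    n_per_group: int = 15
    seed: int = 0
    timepoints: tuple[str, ...] = ("6mo", "10mo")
    tl_mean_mm: Mapping[str, float] = field(
        default_factory=lambda: {"6mo": 40.0, "10mo": 42.0}
    )
    tl_sd_mm: float = 1.75
    allometry: Mapping[str, Allometry] = field(default_factory=default_allometry)
    noise_cv: float = 0.05
    # body-mass law: muscle-linked part + non-muscle constant
    bm_muscle_slope_g_per_mm3: float = 4.5e-3
    bm_muscle_x_intercept_mm3: float = 14000.0
    bm_muscle_atrophy_dmd: float = 0.70
    bm_muscle_cv: float = 0.02  # total-musculature noise averages over many muscles
    bm_constant_g: float = 275.0
    bm_constant_cv: float = 0.04
    ecg: EcgParams = EcgParams()
    breath: BreathParams = BreathParams()
    trials: TrialParams = TrialParams()

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise GenerationError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise GenerationError("noise_cv must be >= 0")
        if self.tl_sd_mm < 0:
            raise GenerationError("tl_sd_mm must be >= 0")
        for tp in self.timepoints:
            if tp not in self.tl_mean_mm:
                raise GenerationError(f"no tl_mean_mm entry for timepoint {tp!r}")

    def with_(self, **kw) -> "SynthesisRecipe":
        """Return a copy with fields replaced (convenience for tests)."""
        return replace(self, **kw)


# --------------------------------------------------------------------------
# animals


def gen_animals(
    recipe: SynthesisRecipe, rng: np.random.Generator | None = None
) -> list[AnimalRecord]:
    """Generate the cohort (both genotypes, all timepoints).

    Organ masses follow ``slope * (TL^3 - x_intercept) * atrophy * (1+eps)``
    with ``eps ~ N(0, noise_cv)``; body mass is the muscle-linked law plus a
    noisy non-muscle constant.  Identical recipe and seed give identical
    cohorts.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    records: list[AnimalRecord] = []
    for tp in recipe.timepoints:
        for genotype in ("WT", "DMD"):
            for i in range(recipe.n_per_group):
                tl = float(rng.normal(recipe.tl_mean_mm[tp], recipe.tl_sd_mm))
                tl3 = tl**3
                organs: dict[str, float] = {}
                for organ, law in recipe.allometry.items():
                    if tl3 <= law.x_intercept_mm3:
                        raise GenerationError(
                            f"TL^3 = {tl3:.0f} mm^3 <= x_intercept "
                            f"{law.x_intercept_mm3:.0f} for organ {organ!r}; "
                            "increase tl_mean_mm or lower the x_intercept"
                        )
                    atrophy = law.atrophy_dmd if genotype == "DMD" else 1.0
                    eps = rng.normal(0.0, recipe.noise_cv) if recipe.noise_cv else 0.0
                    mass = law.slope_g_per_mm3 * (tl3 - law.x_intercept_mm3) * atrophy * (1 + eps)
                    if mass <= 0:
                        raise GenerationError(
                            f"non-positive generated mass for organ {organ!r}; "
                            "reduce noise_cv or adjust the allometry"
                        )
                    organs[organ] = mass
                bm_atrophy = recipe.bm_muscle_atrophy_dmd if genotype == "DMD" else 1.0
                eps_m = rng.normal(0.0, recipe.bm_muscle_cv) if recipe.bm_muscle_cv else 0.0
                eps_c = rng.normal(0.0, recipe.bm_constant_cv) if recipe.bm_constant_cv else 0.0
                if tl3 <= recipe.bm_muscle_x_intercept_mm3:
                    raise GenerationError(
                        "TL^3 below the body-mass x_intercept; adjust tl_mean_mm"
                    )
                bm = (
                    recipe.bm_muscle_slope_g_per_mm3
                    * (tl3 - recipe.bm_muscle_x_intercept_mm3)
                    * bm_atrophy
                    * (1 + eps_m)
                    + recipe.bm_constant_g * (1 + eps_c)
                )
                if bm <= 0:
                    raise GenerationError("non-positive generated body mass")
                records.append(
                    AnimalRecord(
                        animal_id=f"{genotype}-{i + 1:03d}",
                        genotype=genotype,
                        timepoint=tp,
                        tibia_length_mm=tl,
                        body_mass_g=bm,
                        organ_masses_g=organs,
                    )
                )
    return records


# --------------------------------------------------------------------------
# ECG


def _notch_sigma(offset_ms: float, depth: float, amp_ratio: float) -> float:
    """Width of the two T bumps giving the requested notch depth.

    ``depth`` is the dip below the LOWER of the two T maxima, as a fraction
    of the taller maximum — i.e. the topographic prominence of the second
    bump, which is what makes a notch a distinct second peak.  For bumps of
    unit and ``rho`` amplitude separated by ``d``, with
    ``x = exp(-d^2 / (8 sigma^2))``:

        peak1 ~= 1 + rho*x^4,  peak2 ~= rho + x^4,  dip ~= (1 + rho)*x,

    and ``(peak2 - dip) / peak1 = depth`` is solved for ``x`` (monotone) by
    bisection, then inverted for sigma.
    """
    if not 0 < depth < min(1.0, amp_ratio):
        raise GenerationError(
            f"notch_depth must be in (0, {min(1.0, amp_ratio):.2f}) for "
            f"amp_ratio {amp_ratio}"
        )
    d = offset_ms
    rho = amp_ratio

    def f(x: float) -> float:
        return (rho + x**4 - (1 + rho) * x) / (1 + rho * x**4) - depth

    x = brentq(f, 1e-9, 1 - 1e-9)
    return float(np.sqrt(d**2 / (8 * np.log(1 / x))))


def clean_cycle(t_ms: np.ndarray, params: EcgParams, notched: bool) -> np.ndarray:
    """Noise-free single-cycle waveform (mV, baseline 0) at times relative
    to the R peak (ms)."""
    t_ms = np.asarray(t_ms, dtype=float)
    v = np.zeros_like(t_ms)
    for w in (params.p, params.q, params.r, params.s):
        v += w.amp_mv * np.exp(-((t_ms - w.center_ms) ** 2) / (2 * w.sigma_ms**2))
    tw = params.t
    if not notched:
        v += tw.amp_mv * np.exp(-((t_ms - tw.center_ms) ** 2) / (2 * tw.sigma_ms**2))
    else:
        sig = _notch_sigma(
            params.notch_offset_ms, params.notch_depth, params.notch_amp_ratio
        )
        c1 = tw.center_ms - params.notch_offset_ms / 2
        c2 = tw.center_ms + params.notch_offset_ms / 2
        pair = np.exp(-((t_ms - c1) ** 2) / (2 * sig**2)) + params.notch_amp_ratio * np.exp(
            -((t_ms - c2) ** 2) / (2 * sig**2)
        )
        # rescale so the taller bump reaches the nominal T amplitude
        dense = np.arange(c1 - 4 * sig, c2 + 4 * sig, 0.01)
        peak = np.max(
            np.exp(-((dense - c1) ** 2) / (2 * sig**2))
            + params.notch_amp_ratio * np.exp(-((dense - c2) ** 2) / (2 * sig**2))
        )
        v += tw.amp_mv / peak * pair
    return v


# landmark-truth scan windows (ms relative to R); shared with ecg analysis
QRS_ONSET_SEARCH_MS = 20.0
T_SEARCH_MS = (15.0, 90.0)
ONSET_THRESHOLD_FRAC = 0.05


def _cycle_truth(params: EcgParams, notched: bool) -> dict[str, float]:
    """Brute-force landmark ground truth from a densely sampled clean cycle."""
    step = 0.02  # ms
    t = np.arange(-60.0, 110.0 + step, step)
    v = clean_cycle(t, params, notched)
    r_amp = float(v[np.argmin(np.abs(t))])
    thr = ONSET_THRESHOLD_FRAC * r_amp
    pre = (t >= -QRS_ONSET_SEARCH_MS) & (t <= 0)
    idx = np.nonzero(np.abs(v[pre]) > thr)[0]
    if idx.size == 0:
        raise GenerationError("no Q onset found in the clean cycle")
    q_onset = float(t[pre][idx[0]])
    twin = (t >= T_SEARCH_MS[0]) & (t <= T_SEARCH_MS[1])
    t_peak = float(t[twin][np.argmax(np.abs(v[twin]))])
    # count strict local maxima above baseline inside the T window
    vt = v[twin]
    interior = (vt[1:-1] > vt[:-2]) & (vt[1:-1] > vt[2:]) & (vt[1:-1] > 0)
    n_t_maxima = int(np.count_nonzero(interior))
    return {
        "q_onset_ms": q_onset,
        "t_peak_ms": t_peak,
        "qt_peak_ms": t_peak - q_onset,
        "n_t_maxima": n_t_maxima,
        "r_amp_mv": r_amp,
    }


def gen_ecg(
    recipe: SynthesisRecipe,
    notched: bool = False,
    n_cycles: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[TraceSeries, dict]:
    """Generate an ECG trace and its ground truth.

    Returns ``(trace, truth)`` where ``truth`` holds the true R times (s),
    RR intervals (ms), the baseline (mV) and the clean-cycle landmark table
    (Q onset, T peak, QTpeak in ms relative to R, and the number of T-wave
    local maxima).
    """
    if n_cycles < 3:
        raise GenerationError("n_cycles must be >= 3")
    p = recipe.ecg
    extent = (p.t.center_ms + 3 * p.t.sigma_ms) - (p.p.center_ms - 3 * p.p.sigma_ms)
    if extent >= p.rr_mean_ms:
        raise GenerationError(
            f"wave extent {extent:.0f} ms does not fit in the mean RR interval "
            f"({p.rr_mean_ms:.0f} ms)"
        )
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    rr_ms = p.rr_mean_ms + p.rr_sd_ms * rng.standard_normal(n_cycles - 1)
    rr_ms = np.clip(rr_ms, extent + 5.0, None)
    r_times = 0.2 + np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    fs = p.sampling_rate_hz
    n = int(np.ceil((r_times[-1] + 0.2) * fs)) + 1
    tgrid = np.arange(n) / fs
    v = np.full(n, p.baseline_mv)
    for rt in r_times:
        lo = max(0, int(np.floor((rt - 0.080) * fs)))
        hi = min(n, int(np.ceil((rt + 0.120) * fs)) + 1)
        v[lo:hi] += clean_cycle((tgrid[lo:hi] - rt) * 1000.0, p, notched)
    if p.noise_mv:
        v += p.noise_mv * rng.standard_normal(n)
    trace = TraceSeries(sampling_rate_hz=fs, values=v, signal_kind=ECG_VOLTAGE, units="mV")
    truth = {
        "r_times_s": r_times,
        "rr_ms": rr_ms,
        "baseline_mv": p.baseline_mv,
        "notched": notched,
        **_cycle_truth(p, notched),
    }
    return trace, truth


# --------------------------------------------------------------------------
# ventilatory flow


def gen_flow(
    recipe: SynthesisRecipe,
    n_breaths: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[TraceSeries, pd.DataFrame]:
    """Generate a box-flow trace (negative flow = inspiration) plus a
    per-breath ground-truth table (onset, PIF, Ti, tidal volume).

    Inspiration is a negative half-sine of amplitude ``A`` and duration
    ``Ti`` (tidal volume ``2*A*Ti/pi`` exactly); expiration is a positive
    half-sine of equal area followed by a pause.
    """
    if n_breaths < 1:
        raise GenerationError("n_breaths must be >= 1")
    p = recipe.breath
    if p.amp_ml_s <= 0:
        raise GenerationError("inspiratory amplitude must be > 0 (flat trace rejected)")
    period = 60.0 / p.rate_bpm
    if p.ti_s >= period:
        raise GenerationError(
            f"inspiration time {p.ti_s} s must be shorter than the breath period {period:.3f} s"
        )
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    fs = p.sampling_rate_hz
    pad = 0.1
    n = int(np.ceil((n_breaths * period + 2 * pad) * fs)) + 1
    t = np.arange(n) / fs
    flow = np.zeros(n)
    tv = 2 * p.amp_ml_s * p.ti_s / np.pi
    te = p.exp_fraction * (period - p.ti_s)
    amp_e = tv * np.pi / (2 * te)
    rows = []
    for k in range(n_breaths):
        t0 = pad + k * period
        insp = (t >= t0) & (t < t0 + p.ti_s)
        flow[insp] += -p.amp_ml_s * np.sin(np.pi * (t[insp] - t0) / p.ti_s)
        ex = (t >= t0 + p.ti_s) & (t < t0 + p.ti_s + te)
        flow[ex] += amp_e * np.sin(np.pi * (t[ex] - t0 - p.ti_s) / te)
        rows.append(
            {
                "onset_s": t0,
                "pif_ml_s": p.amp_ml_s,
                "ti_s": p.ti_s,
                "tidal_volume_ml": tv,
            }
        )
    if p.noise_ml_s:
        flow += p.noise_ml_s * rng.standard_normal(n)
    trace = TraceSeries(sampling_rate_hz=fs, values=flow, signal_kind=BOX_FLOW, units="mL/s")
    return trace, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# trials


def gen_trials(
    recipe: SynthesisRecipe,
    trial_kind: str,
    genotype: str = "WT",
    rng: np.random.Generator | None = None,
) -> TrialSeries:
    """Generate a grip, fatigue or force-frequency series for one animal."""
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    p = recipe.trials
    dmd = genotype == "DMD"
    factor = p.dmd_force_factor if dmd else 1.0
    if trial_kind == "grip":
        decay = p.dmd_grip_decay if dmd else p.grip_decay
        base = p.grip_max_mn * factor * decay ** np.arange(p.n_grip)
        x = np.arange(1, p.n_grip + 1, dtype=float)
    elif trial_kind == "fatigue":
        decay = p.dmd_fatigue_decay if dmd else p.fatigue_decay
        base = p.ff_fmax_mn * factor * decay ** np.arange(p.n_fatigue)
        x = np.arange(1, p.n_fatigue + 1, dtype=float)
    elif trial_kind == "force_frequency":
        f = np.asarray(p.frequencies_hz, dtype=float)
        f50 = p.ff_f50_hz + (p.dmd_f50_shift_hz if dmd else 0.0)
        base = p.ff_fmax_mn * factor / (1 + np.exp(-(f - f50) / p.ff_slope_hz))
        x = f
    else:
        raise GenerationError(f"unknown trial_kind {trial_kind!r}")
    if p.noise_cv:
        base = base * (1 + p.noise_cv * rng.standard_normal(base.size))
        base = np.clip(base, 0.0, None)
    return TrialSeries(trial_kind=trial_kind, x=x, force_mn=base)


# --------------------------------------------------------------------------
# histology


def gen_histo(
    abnormal_fraction: float,
    n_events: int,
    fibrosis_fraction: float,
    mask_shape: tuple[int, int] = (200, 200),
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate a fibre-event table and tissue/stained masks.

    The event table has exactly ``round(p * n_events)`` abnormal events; the
    stained mask covers exactly ``round(q * tissue_pixels)`` tissue pixels.

    Returns ``(events, tissue_mask, stained_mask)``.
    """
    if n_events <= 0:
        raise GenerationError("n_events must be > 0")
    if not 0 <= abnormal_fraction <= 1 or not 0 <= fibrosis_fraction <= 1:
        raise GenerationError("fractions must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_abn = int(np.floor(abnormal_fraction * n_events + 0.5))
    cats = np.array(["abnormal"] * n_abn + ["normal_fibre"] * (n_events - n_abn))
    rng.shuffle(cats)
    events = pd.DataFrame(
        {"event_id": [f"ev{i:05d}" for i in range(n_events)], "category": cats}
    )
    tissue = np.ones(mask_shape, dtype=bool)
    n_tissue = tissue.sum()
    n_stained = int(np.floor(fibrosis_fraction * n_tissue + 0.5))
    stained = np.zeros(mask_shape, dtype=bool)
    flat_idx = rng.choice(n_tissue, size=n_stained, replace=False)
    stained.flat[flat_idx] = True
    return events, tissue, stained
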