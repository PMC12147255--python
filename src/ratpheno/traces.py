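"""Sampled traces (ECG voltage, plethysmograph flow) and trial series.

Traces live on disk as two-column CSV (``time_s,value``) with uniform
sampling; in memory they are :class:`TraceSeries` carrying the sampling rate
only — timestamps are implied.  Trial tables (grip repetitions, tetanic
fatigue series, force-frequency points) are :class:`TrialSeries`.

Grip devices commonly report gram-force; forces are held internally in mN and
converted at read time when the force column header says ``force_gf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, TraceShapeError

ECG_VOLTAGE = "ecg_voltage"
BOX_FLOW = "box_flow"
SIGNAL_KINDS = (ECG_VOLTAGE, BOX_FLOW)

GF_TO_MN = 9.80665  # mN per gram-force

#: relative tolerance on sampling uniformity (fraction of the median step)
UNIFORMITY_TOL = 0.01

TRIAL_KINDS = ("grip", "fatigue", "force_frequency")


@dataclass(frozen=True)
class TraceSeries:
    """A uniformly sampled physiological signal."""

    sampling_rate_hz: float
    values: np.ndarray
    signal_kind: str
    units: str

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise FormatError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise FormatError(f"signal_kind must be one of {SIGNAL_KINDS}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise FormatError("trace must be a 1-D sequence of at least 2 samples")
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class TrialSeries:
    """Discrete force measurements: grip trials, fatigue series or a
    force-frequency curve (x = trial index or stimulation frequency, Hz)."""

    trial_kind: str
    x: np.ndarray
    force_mn: np.ndarray

    def __post_init__(self) -> None:
        if self.trial_kind not in TRIAL_KINDS:
            raise TraceShapeError(f"trial_kind must be one of {TRIAL_KINDS}")
        x = np.asarray(self.x, dtype=float)
        f = np.asarray(self.force_mn, dtype=float)
        if x.shape != f.shape or x.ndim != 1:
            raise TraceShapeError("x and force must be 1-D and of equal length")
        if np.any(f < 0):
            raise TraceShapeError("forces must be >= 0")
        if self.trial_kind == "force_frequency" and not np.all(np.diff(x) > 0):
            raise TraceShapeError("force_frequency x axis must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "force_mn", f)


def read_trace(path: str | Path, signal_kind: str, units: str = "") -> TraceSeries:
    """Read a two-column ``time_s,value`` CSV as a uniformly sampled trace.

    The sampling rate is inferred from the median time step; any step
    deviating from the median by more than 1% is rejected as non-uniform.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"trace file {path}: empty file") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"trace file {path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"trace file {path}: need at least 2 samples, got {t.size}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"trace file {path}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > UNIFORMITY_TOL * med:
        raise FormatError(
            f"trace file {path}: non-uniform sampling "
            f"(max deviation {np.max(np.abs(dt - med)):.3g} s exceeds 1% of the "
            f"median step {med:.3g} s)"
        )
    return TraceSeries(
        sampling_rate_hz=1.0 / med, values=v, signal_kind=signal_kind, units=units
    )


def write_trace(trace: TraceSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "value": trace.values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_trials(path: str | Path, trial_kind: str) -> TrialSeries:
    """Read a trial CSV.

    Expected columns: ``x`` (trial index or frequency_hz) and one of
    ``force_mn`` / ``force_gf``; gram-force is converted to mN on read.
    """
    df = pd.read_csv(path)
    xcol = "frequency_hz" if "frequency_hz" in df.columns else "x"
    if xcol not in df.columns:
        raise TraceShapeError(f"trial file {path}: missing column 'x' or 'frequency_hz'")
    if "force_mn" in df.columns:
        force = df["force_mn"].to_numpy(dtype=float)
    elif "force_gf" in df.columns:
        force = df["force_gf"].to_numpy(dtype=float) * GF_TO_MN
    else:
        raise TraceShapeError(f"trial file {path}: missing column 'force_mn' or 'force_gf'")
    return TrialSeries(trial_kind=trial_kind, x=df[xcol].to_numpy(dtype=float), force_mn=force)


def write_trials(trials: TrialSeries, path: str | Path) -> None:
    xname = "frequency_hz" if trials.trial_kind == "force_frequency" else "x"
    pd.DataFrame({xname: trials.x, "force_mn": trials.force_mn}).to_csv(
        path, index=False, float_format="%.12g"
    )
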