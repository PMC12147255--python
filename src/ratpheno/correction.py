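"""Growth-disparity correction by cubic tibia length (TL^3).

Dystrophic muscle atrophy makes body mass unusable as a growth reference, so
mass and force variables are normalized against bone growth instead: the
corrector is the cubic tibia length (a mass scales with a volume).  For each
variable a linear regression is fitted in healthy (WT) animals,

    variable = slope * corrector + intercept,    X_int = -intercept / slope,

and an individual's value is rescaled along that regression line to the
pooled per-timepoint median of the corrector:

    corrected = raw / (corrector_i - X_int) * (median_tp - X_int)

The median is taken over WT and DMD together at the timepoint, so the
corrected value equals the raw value for an animal sitting exactly at the
subgroup median, and the correction is a pure rescaling (multiplying all raw
values by c multiplies corrected values by c).

``split_half_validation`` reproduces the method's validation design: split
the WT group at the body-mass median and check that a properly corrected
variable no longer differs between the light and heavy halves, whereas raw
values (and body-mass- or uncubed-TL-corrected ones) do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)
from .records import AnimalRecord
from . import stats as _stats

CORRECTOR_TL3 = "TL3"
CORRECTOR_TL = "TL"
CORRECTOR_BM = "BM"


def corrector_value(record: AnimalRecord, corrector: str = CORRECTOR_TL3) -> float:
    """Extract an animal's corrector value (TL3 in mm^3, TL in mm, BM in g)."""
    if corrector == CORRECTOR_TL3:
        return record.tibia_length_mm**3
    if corrector == CORRECTOR_TL:
        return record.tibia_length_mm
    if corrector == CORRECTOR_BM:
        return record.body_mass_g
    raise ConfigurationError(f"unknown corrector {corrector!r}")


def variable_value(record: AnimalRecord, variable: str) -> float | None:
    """Look up a correctable variable on a record.

    ``body_mass_g`` and any organ name (or ``<organ>_mass_g``) are accepted;
    returns None if the organ is absent.
    """
    if variable == "body_mass_g":
        return record.body_mass_g
    name = variable[: -len("_mass_g")] if variable.endswith("_mass_g") else variable
    return record.organ_masses_g.get(name)


@dataclass(frozen=True)
class CorrectionModel:
    """WT-fitted regression of one variable on the corrector."""

    variable_name: str
    corrector_name: str
    slope: float
    x_intercept: float
    fit_n: int
    fit_group: str = "WT"

    def __post_init__(self) -> None:
        if self.fit_n < 3:
            raise InsufficientDataError("fit_n must be >= 3")
        if not np.isfinite(self.slope) or not np.isfinite(self.x_intercept):
            raise DegenerateFitError("slope and x_intercept must be finite")


@dataclass(frozen=True)
class CorrectionContext:
    """Per-timepoint pooled (WT + DMD) median of the corrector."""

    timepoint: str
    subgroup_median_corrector: float
    pooled_n: int

    def __post_init__(self) -> None:
        if self.pooled_n < 1:
            raise InsufficientDataError("pooled_n must be >= 1")


def fit_corrector(
    wt_records: Sequence[AnimalRecord],
    variable: str,
    corrector: str = CORRECTOR_TL3,
) -> CorrectionModel:
    """Ordinary least-squares fit of ``variable`` on the corrector in WT.

    The X-intercept of the fitted line (corrector value at which the
    variable extrapolates to zero) is the correction origin.
    """
    xs, ys = [], []
    for r in wt_records:
        if r.genotype != "WT":
            continue
        y = variable_value(r, variable)
        if y is None:
            continue
        xs.append(corrector_value(r, corrector))
        ys.append(y)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need >= 3 WT records with {variable!r}; got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"all WT records share the same {corrector} value; regression undefined"
        )
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) < 1e-12:
        raise DegenerateFitError(
            f"fitted slope {slope:.3g} for {variable!r} is indistinguishable from 0"
        )
    return CorrectionModel(
        variable_name=variable,
        corrector_name=corrector,
        slope=float(slope),
        x_intercept=float(-intercept / slope),
        fit_n=len(xs),
    )


def subgroup_median(
    records: Sequence[AnimalRecord],
    timepoint: str,
    corrector: str = CORRECTOR_TL3,
) -> CorrectionContext:
    """Median corrector over ALL genotypes at one timepoint.

    Pooling WT and DMD keeps the rescaling target a single constant per
    timepoint.  Even counts use the mean of the central pair.
    """
    vals = [
        corrector_value(r, corrector) for r in records if r.timepoint == timepoint
    ]
    if not vals:
        raise InsufficientDataError(f"no records at timepoint {timepoint!r}")
    return CorrectionContext(
        timepoint=timepoint,
        subgroup_median_corrector=float(np.median(vals)),
        pooled_n=len(vals),
    )


def correct_value(
    raw: float,
    corrector_value_: float,
    model: CorrectionModel,
    context: CorrectionContext,
) -> float:
    """Apply the correction formula to one raw value.

    corrected = raw / (corrector - X_int) * (median - X_int)

    Raises :class:`DomainError` if the animal's corrector does not exceed the
    X-intercept (the regression predicts non-positive mass there), and
    :class:`ConfigurationError` for a context median at or below it.
    """
    denom = corrector_value_ - model.x_intercept
    if denom <= 0:
        raise DomainError(
            f"corrector value {corrector_value_:.6g} <= x_intercept "
            f"{model.x_intercept:.6g}; animal below the regression's zero-mass size"
        )
    numer = context.subgroup_median_corrector - model.x_intercept
    if numer <= 0:
        raise ConfigurationError(
            f"subgroup median {context.subgroup_median_corrector:.6g} <= x_intercept "
            f"{model.x_intercept:.6g} at timepoint {context.timepoint!r}"
        )
    return raw / denom * numer


def correct_cohort(
    records: Sequence[AnimalRecord],
    variables: Sequence[str],
    models: Mapping[str, CorrectionModel],
    contexts: Mapping[str, CorrectionContext],
) -> pd.DataFrame:
    """Correct every (animal, variable) pair into a long-format table.

    Rows whose corrector falls at/below the model's X-intercept are flagged
    ``domain_error`` (with corrected = NaN) rather than dropped.
    """
    for v in variables:
        if v not in models:
            raise ConfigurationError(f"no CorrectionModel supplied for variable {v!r}")
    rows = []
    for r in records:
        if r.timepoint not in contexts:
            raise ConfigurationError(f"no CorrectionContext for timepoint {r.timepoint!r}")
        for v in variables:
            raw = variable_value(r, v)
            if raw is None:
                continue
            model = models[v]
            cv = corrector_value(r, model.corrector_name)
            try:
                corrected = correct_value(raw, cv, model, contexts[r.timepoint])
                flag = ""
            except DomainError:
                corrected = float("nan")
                flag = "domain_error"
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "genotype": r.genotype,
                    "timepoint": r.timepoint,
                    "variable": v,
                    "raw": raw,
                    "corrected": corrected,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "timepoint", "variable", "raw", "corrected", "flag"],
    )


def fit_models_and_contexts(
    records: Sequence[AnimalRecord],
    variables: Sequence[str],
    corrector: str = CORRECTOR_TL3,
) -> tuple[dict[str, CorrectionModel], dict[str, CorrectionContext]]:
    """Convenience: WT-fitted models (pooled across timepoints) plus
    per-timepoint pooled-median contexts for every timepoint present."""
    wt = [r for r in records if r.genotype == "WT"]
    models = {v: fit_corrector(wt, v, corrector) for v in variables}
    contexts = {
        tp: subgroup_median(records, tp, corrector)
        for tp in dict.fromkeys(r.timepoint for r in records)
    }
    return models, contexts


#: correctors applied as the classical ratio normalization (divide by the
#: corrector, i.e. an implicit X-intercept at the origin) in the split-half
#: validation.  Body mass and uncubed tibia length are the conventional
#: growth references; the optimized method is the X-intercept regression on
#: TL^3.
CLASSICAL_CORRECTORS = (CORRECTOR_BM, CORRECTOR_TL)


def split_half_validation(
    wt_records: Sequence[AnimalRecord],
    variable: str,
    correctors: Iterable[str] = (CORRECTOR_BM, CORRECTOR_TL, CORRECTOR_TL3),
    classical: Iterable[str] = CLASSICAL_CORRECTORS,
) -> pd.DataFrame:
    """Light-vs-heavy validation of correction quality within WT.

    Splits the WT animals at the body-mass median (the heavier half gets the
    extra animal on odd counts) and, for the raw variable and each requested
    corrector, reports the two-tailed light-vs-heavy p-value (test family
    chosen by the Shapiro-Wilk gate) and the standardized mean difference.

    Correctors listed in ``classical`` are applied the conventional way —
    plain division by the corrector (rescaled by the cohort median so units
    are preserved), i.e. a rescaling line forced through the origin.  The
    others use the fitted X-intercept formula.  A division-based correction
    fails whenever the variable-vs-corrector line has a non-zero intercept,
    which is exactly what this validation is designed to expose.
    """
    wt = [r for r in wt_records if r.genotype == "WT"]
    if len(wt) < 8:
        raise InsufficientDataError(f"need >= 8 WT records, got {len(wt)}")
    order = np.argsort([r.body_mass_g for r in wt], kind="stable")
    n_light = len(wt) // 2
    light = [wt[i] for i in order[:n_light]]
    heavy = [wt[i] for i in order[n_light:]]

    classical = set(classical)

    def corrected_values(group: Sequence[AnimalRecord], corrector: str | None):
        if corrector is None:
            return np.array([variable_value(r, variable) for r in group], dtype=float)
        if corrector in classical:
            model = CorrectionModel(
                variable_name=variable, corrector_name=corrector,
                slope=1.0, x_intercept=0.0, fit_n=len(wt),
            )
        else:
            model = fit_corrector(wt, variable, corrector)
        ctx_vals = [corrector_value(r, corrector) for r in wt]
        ctx = CorrectionContext(
            timepoint="pooled",
            subgroup_median_corrector=float(np.median(ctx_vals)),
            pooled_n=len(wt),
        )
        return np.array(
            [
                correct_value(
                    variable_value(r, variable), corrector_value(r, corrector), model, ctx
                )
                for r in group
            ]
        )

    rows = []
    for corrector in [None, *correctors]:
        a = corrected_values(light, corrector)
        b = corrected_values(heavy, corrector)
        scale = float(np.max(np.abs(np.concatenate([a, b])))) or 1.0
        if np.ptp(np.concatenate([a, b])) <= 1e-12 * scale:
            # perfectly corrected (constant) values: no difference by definition
            result = _stats.TwoGroupResult("constant", 0.0, 1.0)
            smd = 0.0
        else:
            result = _stats.gated_two_group(a, b)
            pooled_sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
            diff = float(np.mean(b) - np.mean(a))
            smd = 0.0 if abs(diff) < 1e-30 else diff / pooled_sd
        rows.append(
            {
                "corrector": "raw" if corrector is None else corrector,
                "n_light": len(light),
                "n_heavy": len(heavy),
                "test": result.test_name,
                "p_value": result.p_two_tailed,
                "smd": smd,
            }
        )
    return pd.DataFrame(rows)
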