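"""Normality-gated group comparisons with three planned contrasts.

The study design compares WT and DMD rats at 6 and 10 months with exactly
three planned contrasts: WT vs DMD at 6 months, WT vs DMD at 10 months, and
disease progression (DMD 6 vs 10 months).  The test family is gated on
Shapiro-Wilk normality (all groups must pass at alpha 0.05 for the
parametric branch):

* parametric — one-way ANOVA omnibus, then pooled-variance t contrasts with
  Sidak adjustment over the three planned comparisons;
* nonparametric — Kruskal-Wallis omnibus, then Dunn's rank contrasts
  (mid-ranks, tie-corrected variance, standard-normal reference) with the
  same Sidak-style adjustment.

Adjusted p-values are never smaller than unadjusted ones, and the adjustment
spans only the planned contrasts, not all pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError, GateError

ALPHA = 0.05

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"

#: the three planned contrasts: (name, group A, group B)
PLANNED_CONTRASTS = (
    ("WT6_vs_DMD6", "WT:6mo", "DMD:6mo"),
    ("WT10_vs_DMD10", "WT:10mo", "DMD:10mo"),
    ("DMD6_vs_DMD10", "DMD:6mo", "DMD:10mo"),
)


@dataclass(frozen=True)
class TwoGroupResult:
    test_name: str
    statistic: float
    p_two_tailed: float
    p_one_tailed: float | None = None


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    contrast: str
    test_family: str
    statistic: float
    p_two_tailed: float
    p_adjusted: float
    omnibus_statistic: float
    omnibus_p: float
    n_a: int
    n_b: int
    alpha: float = ALPHA
    skipped: bool = False


def _as_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.ndim != 1 or g.size < 3:
            raise GateError("each group needs n >= 3 one-dimensional samples")
        if np.ptp(g) == 0:
            raise GateError("constant group: normality test undefined")
    return out


def normality_gate(groups: Sequence[np.ndarray], alpha: float = ALPHA) -> str:
    """Choose the test family: parametric iff every group passes
    Shapiro-Wilk at ``alpha``."""
    gs = _as_groups(groups)
    for g in gs:
        if sps.shapiro(g).pvalue <= alpha:
            return NONPARAMETRIC
    return PARAMETRIC


def sidak_adjust(p: float, m: int) -> float:
    """Sidak adjustment of one p-value for a family of ``m`` comparisons."""
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def _pooled_t(groups: Mapping[str, np.ndarray], a: str, b: str) -> tuple[float, float]:
    """Pooled-MSE t contrast across all groups (df = N - k), two-tailed p."""
    k = len(groups)
    ns = {g: len(v) for g, v in groups.items()}
    big_n = sum(ns.values())
    df = big_n - k
    mse = sum(np.var(v, ddof=1) * (len(v) - 1) for v in groups.values()) / df
    ga, gb = groups[a], groups[b]
    se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
    if se == 0:
        raise DegenerateInputError("zero pooled variance across groups")
    t = (np.mean(ga) - np.mean(gb)) / se
    return float(t), float(2 * sps.t.sf(abs(t), df))


def _dunn_z(groups: Mapping[str, np.ndarray], a: str, b: str) -> tuple[float, float]:
    """Dunn's rank contrast on the pooled mid-ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    mean_rank = {}
    start = 0
    for g in labels:
        n = len(groups[g])
        mean_rank[g] = float(np.mean(ranks[start : start + n]))
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (big_n - 1))
    var_unit = big_n * (big_n + 1) / 12.0 - tie_term
    se = np.sqrt(var_unit * (1 / len(groups[a]) + 1 / len(groups[b])))
    if se == 0:
        raise DegenerateInputError("all observations tied; rank contrast undefined")
    z = (mean_rank[a] - mean_rank[b]) / se
    return float(z), float(2 * sps.norm.sf(abs(z)))


def planned_contrasts(
    data: Mapping[str, Sequence[float]],
    family: str | None = None,
    variable: str = "",
    contrasts: Sequence[tuple[str, str, str]] = PLANNED_CONTRASTS,
) -> list[ComparisonResult]:
    """Run the omnibus test plus the planned contrasts on labelled groups.

    ``data`` maps group labels (``"WT:6mo"`` ...) to samples.  ``family``
    overrides the Shapiro gate when given.  A contrast whose group is absent
    is returned flagged ``skipped`` rather than silently dropped.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups")
    if family is None:
        family = normality_gate(list(groups.values()))
    elif family not in (PARAMETRIC, NONPARAMETRIC):
        raise ConfigurationError(f"unknown family {family!r}")
    if family == PARAMETRIC:
        om = sps.f_oneway(*groups.values())
    else:
        om = sps.kruskal(*groups.values())
    om_stat, om_p = float(om.statistic), float(om.pvalue)
    doable = [c for c in contrasts if c[1] in groups and c[2] in groups]
    m = max(1, len(doable))
    results = []
    for name, a, b in contrasts:
        if (name, a, b) not in doable:
            results.append(
                ComparisonResult(
                    variable=variable, contrast=name, test_family=family,
                    statistic=float("nan"), p_two_tailed=float("nan"),
                    p_adjusted=float("nan"), omnibus_statistic=om_stat,
                    omnibus_p=om_p, n_a=0, n_b=0, skipped=True,
                )
            )
            continue
        if family == PARAMETRIC:
            stat, p = _pooled_t(groups, a, b)
        else:
            stat, p = _dunn_z(groups, a, b)
        results.append(
            ComparisonResult(
                variable=variable, contrast=name, test_family=family,
                statistic=stat, p_two_tailed=p, p_adjusted=sidak_adjust(p, m),
                omnibus_statistic=om_stat, omnibus_p=om_p,
                n_a=len(groups[a]), n_b=len(groups[b]),
            )
        )
    return results


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: str = "two",
    direction: str = "a_greater",
) -> TwoGroupResult:
    """Unpaired t test between two samples.

    ``sidedness="one"`` tests the alternative given by ``direction``
    (``"a_greater"`` or ``"b_greater"``); the two-tailed p is always
    reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each sample needs n >= 2")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateInputError("zero pooled variance")
    res = sps.ttest_ind(a, b)
    p_two = float(res.pvalue)
    p_one = None
    if sidedness == "one":
        alt = "greater" if direction == "a_greater" else "less"
        p_one = float(sps.ttest_ind(a, b, alternative=alt).pvalue)
    elif sidedness != "two":
        raise ConfigurationError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    return TwoGroupResult(
        test_name="t_unpaired", statistic=float(res.statistic),
        p_two_tailed=p_two, p_one_tailed=p_one,
    )


def gated_two_group(a: Sequence[float], b: Sequence[float]) -> TwoGroupResult:
    """Two-group comparison with the Shapiro gate: unpaired t when both
    samples look normal, Mann-Whitney U otherwise (two-tailed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    family = normality_gate([a, b])
    if family == PARAMETRIC:
        res = sps.ttest_ind(a, b)
        return TwoGroupResult("t_unpaired", float(res.statistic), float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TwoGroupResult("mannwhitney_u", float(res.statistic), float(res.pvalue))
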