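"""TL^3 growth-correction: exact identities, regression recovery, and the
split-half validation conventions."""

import numpy as np
import pytest

from ratpheno.correction import (
    CorrectionContext,
    CorrectionModel,
    correct_cohort,
    correct_value,
    fit_corrector,
    fit_models_and_contexts,
    split_half_validation,
    subgroup_median,
)
from ratpheno.errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)
from ratpheno.records import AnimalRecord
from ratpheno.synth import gen_animals


def _wt(tl, variable, animal_id="a", timepoint="6mo", bm=500.0):
    return AnimalRecord(animal_id, "WT", timepoint, tl, bm, {"ta": variable})


def _linear_cohort(tls, slope=2e-5, x_int=14000.0):
    return [
        _wt(tl, slope * (tl**3 - x_int), animal_id=f"a{i}")
        for i, tl in enumerate(tls)
    ]


class TestFitCorrector:
    def test_exact_line_recovery(self):
        records = _linear_cohort([38.0, 40.0, 42.0, 44.0])
        model = fit_corrector(records, "ta_mass_g")
        assert model.slope == pytest.approx(2e-5, rel=1e-9)
        assert model.x_intercept == pytest.approx(14000.0, rel=1e-9)

    def test_zero_variance_regressor_degenerate(self):
        records = _linear_cohort([40.0, 40.0, 40.0])
        with pytest.raises(DegenerateFitError):
            fit_corrector(records, "ta_mass_g")

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            fit_corrector(_linear_cohort([40.0, 42.0]), "ta_mass_g")

    def test_x_intercept_bootstrap_ci_covers_generative_value(self):
        """WT fits on 60 noisy animals: a brute-force nonparametric
        bootstrap 95% CI (10,000 resamples) around the fitted x-intercept
        covers the generative 14,000 mm^3 at about the nominal rate."""
        from ratpheno.synth import SynthesisRecipe

        rng = np.random.default_rng(0)
        covered = 0
        n_cohorts = 20
        for s in range(n_cohorts):
            rec = SynthesisRecipe(
                seed=100 + s, n_per_group=60, timepoints=("6mo",),
                tl_mean_mm={"6mo": 40.0},
            )
            wt = [a for a in gen_animals(rec) if a.genotype == "WT"]
            model = fit_corrector(wt, "ta_mass_g")
            x = np.array([a.tibia_length_mm**3 for a in wt])
            y = np.array([a.organ_masses_g["ta"] for a in wt])
            idx = rng.integers(0, len(x), size=(10_000, len(x)))
            xs, ys = x[idx], y[idx]
            vx = xs - xs.mean(axis=1, keepdims=True)
            slope = np.einsum("ij,ij->i", vx, ys - ys.mean(axis=1, keepdims=True))
            slope /= np.einsum("ij,ij->i", vx, vx)
            intercept = ys.mean(axis=1) - slope * xs.mean(axis=1)
            boots = -intercept / slope
            lo, hi = np.percentile(boots, [2.5, 97.5])
            assert lo <= model.x_intercept <= hi  # CI centers on the fit
            covered += lo <= 14000.0 <= hi
        assert covered >= 16  # ~95% nominal coverage, 20 cohorts


class TestSubgroupMedian:
    def test_odd_count(self):
        records = _linear_cohort([40.0, 42.0, 44.0])
        ctx = subgroup_median(records, "6mo")
        assert ctx.subgroup_median_corrector == pytest.approx(42.0**3)

    def test_even_count_mean_of_central_pair(self):
        records = _linear_cohort([40.0, 44.0])
        ctx = subgroup_median(records, "6mo")
        assert ctx.subgroup_median_corrector == pytest.approx((64000.0 + 85184.0) / 2)

    def test_pooled_over_genotypes(self):
        recs = _linear_cohort([40.0, 42.0])
        recs.append(AnimalRecord("d", "DMD", "6mo", 44.0, 400.0, {"ta": 0.5}))
        ctx = subgroup_median(recs, "6mo")
        assert ctx.pooled_n == 3
        assert ctx.subgroup_median_corrector == pytest.approx(42.0**3)

    def test_empty_timepoint(self):
        with pytest.raises(InsufficientDataError):
            subgroup_median(_linear_cohort([40.0]), "10mo")


class TestCorrectValue:
    MODEL = CorrectionModel("ta_mass_g", "TL3", slope=2e-5, x_intercept=0.0, fit_n=10)

    def test_fixed_point_at_median(self):
        ctx = CorrectionContext("6mo", 64000.0, 10)
        assert correct_value(1.234, 64000.0, self.MODEL, ctx) == 1.234

    def test_direct_arithmetic(self):
        ctx = CorrectionContext("6mo", 4.0, 10)
        assert correct_value(1.0, 2.0, self.MODEL, ctx) == pytest.approx(2.0)

    def test_scale_equivariance(self):
        ctx = CorrectionContext("6mo", 70000.0, 10)
        c1 = correct_value(1.0, 60000.0, self.MODEL, ctx)
        c7 = correct_value(7.0, 60000.0, self.MODEL, ctx)
        assert c7 == pytest.approx(7.0 * c1, rel=1e-12)

    def test_domain_error_below_intercept(self):
        model = CorrectionModel("ta_mass_g", "TL3", 2e-5, 64000.0, 10)
        ctx = CorrectionContext("6mo", 70000.0, 10)
        with pytest.raises(DomainError):
            correct_value(1.0, 64000.0, model, ctx)

    def test_noiseless_cohort_collapses(self, noiseless_recipe):
        """Under the exact linear law, corrected values are constant within
        genotype regardless of TL (relative spread < 1e-9)."""
        rec = noiseless_recipe.with_(tl_sd_mm=2.0)
        animals = gen_animals(rec)
        models, contexts = fit_models_and_contexts(animals, ["ta_mass_g"])
        table = correct_cohort(animals, ["ta_mass_g"], models, contexts)
        for (gt, tp), sub in table.groupby(["genotype", "timepoint"]):
            vals = sub["corrected"].to_numpy()
            assert np.ptp(vals) / np.mean(vals) < 1e-9


class TestCorrectCohort:
    def test_cardinality(self):
        records = _linear_cohort([40.0, 42.0, 44.0])
        for r in records:
            r.organ_masses_g["heart"] = 2.6e-5 * (r.tibia_length_mm**3 - 14000.0)
        models, contexts = fit_models_and_contexts(records, ["ta_mass_g", "heart_mass_g"])
        table = correct_cohort(records[:2], ["ta_mass_g", "heart_mass_g"], models, contexts)
        assert len(table) == 4

    def test_domain_violation_flagged_not_dropped(self):
        records = _linear_cohort([40.0, 42.0, 44.0])
        model = CorrectionModel("ta_mass_g", "TL3", 2e-5, 40.0**3, 10)
        ctx = {"6mo": CorrectionContext("6mo", 42.0**3, 3)}
        table = correct_cohort(records, ["ta_mass_g"], {"ta_mass_g": model}, ctx)
        flagged = table[table["flag"] == "domain_error"]
        assert len(flagged) == 1
        assert flagged["animal_id"].iloc[0] == "a0"
        assert np.isnan(flagged["corrected"].iloc[0])

    def test_missing_model_is_configuration_error(self):
        records = _linear_cohort([40.0, 42.0, 44.0])
        with pytest.raises(ConfigurationError, match="heart_mass_g"):
            correct_cohort(records, ["heart_mass_g"], {}, {})

    def test_correction_reduces_wt_cv(self, one_timepoint_recipe):
        rec = one_timepoint_recipe.with_(noise_cv=0.02)
        animals = [a for a in gen_animals(rec) if a.genotype == "WT"]
        models, contexts = fit_models_and_contexts(animals, ["ta_mass_g"])
        table = correct_cohort(animals, ["ta_mass_g"], models, contexts)
        cv = lambda v: np.std(v) / np.mean(v)
        assert cv(table["corrected"]) < cv(table["raw"])


class TestSplitHalf:
    def test_noiseless_smd_is_zero(self, noiseless_recipe):
        rec = noiseless_recipe.with_(
            n_per_group=30, tl_sd_mm=2.0, timepoints=("6mo",), tl_mean_mm={"6mo": 40.0}
        )
        animals = [a for a in gen_animals(rec) if a.genotype == "WT"]
        tab = split_half_validation(animals, "ta_mass_g")
        tl3 = tab[tab.corrector == "TL3"]
        assert abs(tl3["smd"].iloc[0]) < 1e-9

    def test_odd_count_heavier_half_gets_extra(self):
        animals = [
            _wt(40.0 + 0.1 * i, 1.0 + 0.01 * i, animal_id=f"a{i}", bm=400.0 + i)
            for i in range(9)
        ]
        tab = split_half_validation(animals, "ta_mass_g", correctors=())
        assert tab["n_light"].iloc[0] == 4
        assert tab["n_heavy"].iloc[0] == 5

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            split_half_validation(_linear_cohort([40.0 + i for i in range(5)]), "ta_mass_g")
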