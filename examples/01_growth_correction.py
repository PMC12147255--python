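"""Growth-disparity correction by cubic tibia length.

Generates a synthetic WT cohort with realistic growth spread, fits the
variable-vs-TL^3 regression, corrects tibialis anterior masses, and runs
the light-vs-heavy split-half validation comparing correctors.
"""

import numpy as np

from ratpheno import SynthesisRecipe, gen_animals, split_half_validation
from ratpheno.correction import correct_cohort, fit_models_and_contexts

recipe = SynthesisRecipe(seed=42, n_per_group=30, timepoints=("6mo",),
                         tl_mean_mm={"6mo": 40.0})
animals = [a for a in gen_animals(recipe) if a.genotype == "WT"]

models, contexts = fit_models_and_contexts(animals, ["ta_mass_g"])
m = models["ta_mass_g"]
print(f"WT fit: slope = {m.slope:.3e} g/mm^3, X-intercept = {m.x_intercept:.0f} mm^3")
print("(the regression's X-intercept is the corrector value at which the "
      "organ mass extrapolates to zero — the origin of the rescaling)")

table = correct_cohort(animals, ["ta_mass_g"], models, contexts)
cv = lambda v: np.std(v) / np.mean(v) * 100
print(f"\nTA mass spread across WT: raw CV = {cv(table['raw']):.1f}% -> "
      f"corrected CV = {cv(table['corrected']):.1f}%")

print("\nSplit-half validation (light vs heavy half at the body-mass median):")
val = split_half_validation(animals, "ta_mass_g")
for _, row in val.iterrows():
    verdict = "differs" if row.p_value < 0.05 else "homogeneous"
    print(f"  {row.corrector:>4}: p = {row.p_value:.4f}, smd = {row.smd:+.2f}  -> {verdict}")
print("Only the TL^3 correction removes the growth-linked difference; the "
      "classical body-mass and tibia-length ratios do not.")
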