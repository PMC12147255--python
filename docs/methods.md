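# Methods

This note documents the models and procedures implemented in `ratpheno`,
the synthetic world they are verified against, and the choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Growth-disparity correction

Longitudinal dystrophy studies compare organ masses and force values across
animals whose overall growth differs. The usual normalizations divide by
body mass or by a linear skeletal dimension. Both are problematic here:

* body mass is dominated by striated muscle, which is exactly what the
  disease destroys — a body-mass correction of an unaffected organ
  over-corrects in atrophic animals and fabricates a genotype difference;
* a *ratio* normalization (raw/corrector, rescaled by the cohort median) is
  only valid when the variable-vs-corrector relation passes through the
  origin, which mass-vs-size relations do not.

The implemented correction regresses each variable on the **cubic** tibia
length (a mass scales with a volume, not a length) in healthy animals only,
takes the regression's X-intercept `X_int = −intercept/slope` as the origin
of the rescaling, and maps each animal along the line to the pooled
per-timepoint median of TL³:

```
corrected = raw / (TL³_i − X_int) · (median_TL³(timepoint) − X_int)
```

Properties relied on by the tests: fixed point at the median (exact), scale
equivariance (exact), collapse to a constant under a noiseless linear
generative law (numerically < 1e-9 relative spread), and insensitivity to
atrophy because the corrector is skeletal.

Conventions: models are fitted on WT only, pooled across timepoints;
medians pool both genotypes within a timepoint; even-count medians are the
mean of the central pair; ordinary least squares of the variable on TL³
(the X-intercept lives on the corrector axis, which rules out the reversed
regression); batch correction flags rows whose corrector does not exceed
the X-intercept (`domain_error`) instead of raising, keeping cohort
processing total.

**Split-half validation.** The WT group is split at the body-mass median
(heavier half takes the extra animal on odd counts; minimum 8 animals so
the normality gate is defined on both halves) and light vs heavy are
compared for the raw variable and for each corrector. Body mass and
uncubed tibia length are applied as *classical ratio* corrections — that is
what they are in conventional practice, and a same-cohort X-intercept
regression on any corrector rescales along the conditional mean and so can
never fail this test under joint normality. TL³ uses the full X-intercept
method. The expected pattern — raw, BM-ratio and TL-ratio all significant,
TL³ homogeneous — is a *mechanistic* consequence: the TA-vs-BM line has a
large positive mass offset (non-muscle body mass), and TA is cubic, not
linear, in TL.

## Synthetic cohort generator

The generator is the package's ground truth, not a fixture. It emulates:

* **Animals.** TL ~ Normal(40 mm at 6 months, 42 mm at 10 months; sd
  1.75 mm — a cohort with visible growth disparity, which is the premise of
  the split-half validation). Each organ mass is
  `slope·(TL³ − 14000 mm³)·atrophy·(1+ε)`, ε ~ N(0, noise_cv = 0.05);
  slopes give a ~1.0 g tibialis anterior, ~1.3 g heart, ~1.8 g testis at
  TL = 40 mm. DMD atrophy multipliers: 0.70 (TA, EDL), 0.80 (soleus), 0.85
  (heart), 1.00 (testis — the deliberately unaffected organ).
* **Body mass** = muscle-linked part `4.5e-3 g/mm³ · (TL³ − 14000) ·
  atrophy · (1+ε_m)` plus a non-muscle constant `275 g · (1+ε_c)`. The
  muscle part's CV is 0.02 (total musculature averages over many muscles),
  the constant's CV 0.04 (adiposity/viscera vary independently of bone
  growth); together ~7% body-mass CV at ~500 g, realistic for adult male
  Sprague Dawley rats. The independent non-muscle variance and the large
  mass offset are what make body mass an imperfect corrector in this
  synthetic world; the law is scaffolding for the validation experiments
  and is not a physiological model of body composition.
* **ECG.** Each cycle is a sum of Gaussian bumps for P, Q, R, S, T at fixed
  offsets from the R peak (P −34 ms, Q −8, R 0, S +6, T +45; R amplitude
  1 mV); RR ~ Normal(140 ms, 5 ms) ≈ 430 bpm resting; additive white noise
  0.01 mV. A notched T is a pair of bumps whose spacing is 12 ms and whose
  width is solved (bisection) so that the *second bump's topographic
  prominence* — the dip below the lower maximum — equals the requested
  depth fraction of the T amplitude; that is the quantity a notch detector
  can actually resolve. Landmark ground truth (Q onset, T peak, maxima
  count) is computed by brute-force scan of a 0.02 ms-step noiseless cycle,
  independent of the detector path.
* **Flow.** Inspiration is a negative half-sine (amplitude A = 2 mL/s,
  Ti = 0.2 s, 100 breaths/min), giving the closed-form tidal volume
  `2·A·Ti/π`; expiration is a positive half-sine of equal area followed by
  a pause. The default trace is noise-free (emulating exported, filtered
  instrument output); noise is opt-in.
* **Trials.** Grip and fatigue series decay geometrically (WT 0.95/0.97
  per trial, DMD 0.90/0.93); the force-frequency curve is a logistic in
  frequency (F50 40 Hz, slope 8 Hz, +15 Hz shift and ×0.6 force in DMD)
  evaluated at the ten standard stimulation frequencies.
* **Histology.** Event tables with an exact `round(p·n)` abnormal count and
  masks with an exact `round(q·pixels)` stained count.

What the generator does **not** emulate — hence what passing tests do not
show about real data: electrode artefacts, baseline wander and arrhythmia
in ECG; movement and sigh breaths in plethysmography; nonlinear allometry
and body-composition physiology; correlated longitudinal trajectories
(timepoints are independent draws); segmentation error upstream of the
histology indices.

## ECG analysis choices

* R detection: prominence/height threshold (50% of the largest deviation
  from the median level) with a 50 ms refractory period — adequate for
  clean telemetric traces; parameters exposed.
* Resting selection: instantaneous HR ≤ 1.1 × minimum HR, the lowest-rate
  cycle always included.
* Averaging window (−60, +110) ms covers P-to-T at ~430 bpm. The first
  detected cycle is excluded (no preceding beat, so its pre-R window lacks
  the previous T tail); cycles whose window would overrun a neighbouring R
  or the trace bounds are excluded and counted.
* Isoelectric line: mean over the earliest 15 ms of the window
  (−60 to −45 ms), the TP segment at rat rates; the estimate carries the
  window used and the segment's sd as a noise estimate.
* Q onset: first departure from baseline beyond 5% of the R amplitude
  within the 20 ms QRS search window. T peak: largest deviation from
  baseline in (15, 90) ms; ties go to the earlier maximum. Notch test: two
  peaks (≥ 30% of T amplitude, prominence ≥ 5%, separation ≥ 4 ms after
  1.5 ms smoothing) with the dip between them staying above baseline. The
  smoothing and separation floors exist so that residual averaging noise on
  a flat T top cannot fake a second bump.
* End of QRS: first baseline recrossing after the S trough; for notched
  beats the J point is the first run of ≥ 3 ms with smoothed derivative
  magnitude below 2% of the R amplitude per ms ("return to horizontal").
* QTpc: the two RR quantities in `QTpeak/√(RR/f)` are deliberately
  distinct — RR is the resting-cycle mean, f the whole-recording mean. A
  reading with both equal would force QTpc = QTpeak identically; keeping f
  as the rat's own long-run mean preserves the within-animal rate
  correction while normalizing across animals.

## Physiology and histology choices

* The force-frequency "plateau" is read as the curve maximum
  (deterministic); f50 summarizes the curve's position by linear
  interpolation of the first 50% crossing of the relative curve.
* Breath segmentation smooths with a 25 ms window and drops phases shorter
  than 50 ms (guards against noise-induced zero-crossings), then refines
  phase boundaries to sub-sample zero crossings of the raw trace; tidal
  volume integrates |flow| by the trapezoid rule with the interpolated
  boundary slivers, giving second-order convergence in the sampling step.
  PIF/PEF are extremes of the raw trace (the recorded values). Inspiration
  is the negative phase; traces with the opposite convention are negated at
  load (`invert`).
* Fibrosis is expressed relative to tissue-only area (configurable input
  masks); the event taxonomy behind the pathological index stays upstream —
  the index consumes a binary normal/abnormal classification.

## Statistics choices

* The gate is per-group Shapiro-Wilk; the parametric family requires every
  group to pass at α = 0.05 (conservative and deterministic).
* Parametric contrasts use the pooled mean-square error over all groups
  (df = N − k); nonparametric contrasts are Dunn's z on pooled mid-ranks
  with tie-corrected variance and a standard-normal reference. Both adjust
  with the Sidak formula over exactly the three planned contrasts.
* Calibration is assessed on the *unadjusted* per-contrast p-values (the
  quantity whose size should be α); the Sidak-adjusted p-values control the
  family-wise error across the three contrasts and are checked for
  monotonicity (adjusted ≥ unadjusted). Dunn contrasts between extreme
  groups can saturate in joint ranks — a known limitation of rank-based
  post-hoc tests, visible in the tests.

## Problem sizes

Replicated experiments use 100 synthetic cohorts (60 WT for the split-half,
15/group for the organ-bias contrast), 200 randomized beats of 12 cycles at
2 kHz, 1,000 random RR lists, and 2,000 null replicates of n = 10 per group
for the calibration; the full suite and the reproduction script each run in
well under a minute on a single core.

## Known limitations

* The R-peak detector is not an arrhythmia-grade algorithm; it assumes a
  regular sinus rhythm and a dominant positive R deflection.
* The J-point "return to horizontal" rule is a geometric operationalization
  with configurable ε and run length; other operationalizations exist.
* Correction models assume a single linear mass-TL³ relation pooled across
  ages; age-resolved or nonlinear allometry is out of scope.
* The generator's body-mass law is a validation device, not physiology.
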