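# ratpheno

Analytics for preclinical phenotyping of dystrophic (DMD) rat models:
growth-disparity correction by cubic tibia length, averaged-beat telemetric
ECG analysis with a modified-Bazett corrected QT, grip / tetanic-stimulation
/ whole-body-plethysmography indices, histomorphometric proportions, and the
normality-gated planned group comparisons used to report them. A synthetic
cohort generator reproduces the statistical structure these analyses assume,
so the whole chain is verifiable without animal data.

## Who this is for

Groups running longitudinal rodent studies of muscular dystrophy (or any
disease with progressive atrophy) who need to compare organ masses and
force values across animals of different sizes, and to extract resting ECG
and ventilatory biomarkers from exported telemetry/plethysmography traces.

## The core methods

**TL³ growth correction.** Atrophy makes body mass an invalid growth
reference, and dividing by a corrector fails whenever the organ-vs-corrector
line misses the origin. Instead, for each variable a linear regression is
fitted in healthy (WT) animals against the cubic tibia length
(mass scales with a volume):

    variable = slope · TL³ + intercept,    X_int = −intercept / slope

and each animal's value is rescaled along that line to the pooled
per-timepoint median of TL³:

    corrected = raw / (TL³_individual − X_int) × (median_TL³ − X_int)

An animal at the median keeps its raw value; a noiseless linear cohort
collapses to a constant; multiplying raw values by c multiplies corrected
values by c.

**Averaged-beat ECG with QTpc.** R peaks → resting-cycle selection (heart
rate within 10% of the recording's minimum) → R-aligned averaging over a
(−60, +110) ms window → isoelectric line from the TP segment → landmarks
(Q onset, T peak, S end or — for the dystrophic notched T wave — the J point
as the return of the trace to horizontal). The corrected QT is

    QTpc = QTpeak / √(RR / f)

with RR the mean interval of the selected resting cycles and f the rat's
own mean RR over the whole recording.

**Functional and histological indices.** Grip: max of 5 pulls and the force
maintenance index (mean of the last 3 as % of max). Stimulation:
force–frequency maximum, mass-normalized specific force, interpolated f50,
fatigue FMI (20th contraction as % of max). Plethysmography: PIF/PEF as the
extreme negative/positive flow, inspiration time and tidal volume as the
per-breath integral of inspiratory flow. Histology: pathological index
(% non-normal fibre events) and fibrosis area fraction (% stained tissue
pixels).

**Statistics.** Shapiro-Wilk gates the family: one-way ANOVA with
pooled-variance t contrasts and Sidak adjustment, or Kruskal-Wallis with
Dunn rank contrasts — always over exactly the three planned comparisons
(WT vs DMD at 6 months, at 10 months, and DMD 6 vs 10 months), α = 0.05.

## Worked example

```sh
python examples/02_ecg_averaged_beat.py
```

prints (seed 7):

```
WT-like: 79 cycles, 59 resting-selected, 58 averaged
  Q onset -10.0 ms, T peak +44.5 ms (relative to R), notched T: False
  QTpeak = 54.5 ms, RR(selected) = 140.9 ms, f = 139.0 ms -> QTpc = 54.1 ms
DMD-like: 79 cycles, 63 resting-selected, 62 averaged
  Q onset -10.0 ms, T peak +49.5 ms (relative to R), notched T: True
  QTpeak = 59.5 ms, RR(selected) = 140.6 ms, f = 139.7 ms -> QTpc = 59.3 ms
```

The dystrophic-like trace is classified notched and its rate-corrected
QTpc is ~5 ms longer under matched heart-rate conditions — the
electrocardiographic signature the analysis is built to quantify. The other
examples (`examples/01_…` to `06_…`) walk through the growth correction and
its split-half validation, the functional indices, histology, the gated
statistics, and a full configured pipeline run; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the stages: `ratpheno simulate | correct | ecg | physio
| histo | stats | report` (see `--help`).

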