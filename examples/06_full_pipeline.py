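"""End-to-end configured pipeline run.

Simulates a cohort, corrects organ masses, analyzes ECG traces, computes
physiological and histological metrics and the group statistics, writing
per-stage CSVs plus a log under ./pipeline_output.
"""

from ratpheno import run_pipeline

config = {
    "seed": 1,
    "stages": ["simulate", "correct", "ecg", "physio", "histo", "stats", "report"],
    "simulate": {"n_per_group": 10},
}
results = run_pipeline(config, out_dir="pipeline_output")

print("cohort:", len(results["cohort"]), "animal-timepoint rows")
print("corrected:", len(results["corrected"]), "long-format rows")
print("\nECG features per trace:")
print(results["ecg_features"][["trace", "qt_peak_ms", "qtpc_ms", "notched_t"]]
      .to_string(index=False))
print("\nstats (per variable and contrast):")
print(results["stats"][["variable", "contrast", "test_family", "p_adjusted"]]
      .to_string(index=False))
print("\nOutputs written under ./pipeline_output (cohort.csv, corrected.csv,"
      " ecg_features.csv, physio.csv, histo.csv, stats.csv, summary.csv, log.json)")
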