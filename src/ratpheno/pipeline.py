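"""Pipeline orchestration: chain simulation, correction, ECG, physiology,
histology and statistics from one configuration.

A configuration is a plain dict (usually loaded from YAML) with a ``seed``,
a ``stages`` list and one optional section per stage.  Stage prerequisites
are validated before any computation starts, outputs are written as CSV
under the output directory with 12-significant-digit formatting (so a rerun
with the same config is byte-identical), and a ``log.json`` records the
package version, seed and the full parameter set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import correct_cohort, fit_models_and_contexts
from .ecg import analyze_ecg
from .errors import ConfigurationError
from .histo import fibrosis_fraction, pathological_index, write_mask_csv
from .physio import breath_metrics, grip_metrics, stim_metrics
from .records import cohort_frame, read_cohort, write_cohort
from .stats import planned_contrasts
from .synth import (
    BreathParams,
    EcgParams,
    SynthesisRecipe,
    TrialParams,
    gen_animals,
    gen_ecg,
    gen_flow,
    gen_histo,
    gen_trials,
)
from .traces import read_trace, write_trace, write_trials

logger = logging.getLogger("ratpheno")

ALL_STAGES = ("simulate", "correct", "ecg", "physio", "histo", "stats", "report")

_FLOAT_FMT = "%.12g"


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    return cfg


def _build_recipe(section: dict, seed: int) -> SynthesisRecipe:
    section = dict(section or {})
    nested = {"ecg": EcgParams, "breath": BreathParams, "trials": TrialParams}
    kwargs: dict = {"seed": seed}
    for key, val in section.items():
        if key in nested:
            kwargs[key] = nested[key](**val)
        elif key == "timepoints":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return SynthesisRecipe(**kwargs)


def _validate(cfg: dict) -> list[str]:
    stages = list(cfg.get("stages", []))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
    have_sim = "simulate" in stages
    if "correct" in stages and not have_sim and not (cfg.get("correct") or {}).get("cohort"):
        raise ConfigurationError("stage 'correct' needs the simulate stage or correct.cohort")
    if "ecg" in stages and not have_sim and not (cfg.get("ecg") or {}).get("traces"):
        raise ConfigurationError("stage 'ecg' needs the simulate stage or ecg.traces")
    if "physio" in stages and not have_sim:
        phys = cfg.get("physio") or {}
        if not any(k in phys for k in ("grip", "ff", "flow")):
            raise ConfigurationError("stage 'physio' needs the simulate stage or input files")
    if "histo" in stages and not have_sim and not (cfg.get("histo") or {}).get("events"):
        raise ConfigurationError("stage 'histo' needs the simulate stage or histo.events")
    if "stats" in stages and "correct" not in stages:
        raise ConfigurationError("stage 'stats' needs the correct stage")
    return stages


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns a dict of result tables.

    ``out_dir`` (or ``config['out']``) receives per-stage CSV outputs plus
    ``log.json``; with neither given, results stay in memory only.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    stages = _validate(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "")) if (out_dir or cfg.get("out")) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    recipe = _build_recipe(cfg.get("simulate", {}), seed)
    records = None
    traces: dict[str, object] = {}

    if "simulate" in stages:
        logger.info("simulate: n_per_group=%d seed=%d", recipe.n_per_group, seed)
        rng = np.random.default_rng(seed)
        records = gen_animals(recipe, rng=rng)
        results["cohort"] = cohort_frame(records)
        ecg_wt, truth_wt = gen_ecg(recipe, notched=False, n_cycles=100, rng=rng)
        ecg_dmd, truth_dmd = gen_ecg(recipe, notched=True, n_cycles=100, rng=rng)
        flow, breath_truth = gen_flow(recipe, n_breaths=20, rng=rng)
        traces = {"ecg_WT": ecg_wt, "ecg_DMD": ecg_dmd, "flow": flow}
        trials = {
            (gt, kind): gen_trials(recipe, kind, genotype=gt, rng=rng)
            for gt in ("WT", "DMD")
            for kind in ("grip", "force_frequency", "fatigue")
        }
        results["trials"] = trials
        histo_cfg = cfg.get("simulate", {}).get("histo", {})
        p_abn = {"WT": 0.03, "DMD": 0.40} | dict(histo_cfg.get("abnormal_fraction", {}))
        q_fib = {"WT": 0.02, "DMD": 0.15} | dict(histo_cfg.get("fibrosis_fraction", {}))
        histo = {
            gt: gen_histo(p_abn[gt], 500, q_fib[gt], rng=rng) for gt in ("WT", "DMD")
        }
        results["histo_inputs"] = histo
        results["ecg_truth"] = {"WT": truth_wt, "DMD": truth_dmd}
        results["breath_truth"] = breath_truth
        if out:
            write_cohort(records, out / "cohort.csv")
            (out / "traces").mkdir(exist_ok=True)
            for name, tr in traces.items():
                write_trace(tr, out / "traces" / f"{name}.csv")
            (out / "trials").mkdir(exist_ok=True)
            for (gt, kind), ts in trials.items():
                write_trials(ts, out / "trials" / f"{gt}_{kind}.csv")
            (out / "histo").mkdir(exist_ok=True)
            for gt, (events, tissue, stained) in histo.items():
                events.to_csv(out / "histo" / f"{gt}_events.csv", index=False)
                write_mask_csv(tissue, out / "histo" / f"{gt}_tissue.csv")
                write_mask_csv(stained, out / "histo" / f"{gt}_stained.csv")
            (out / "ground_truth").mkdir(exist_ok=True)
            breath_truth.to_csv(
                out / "ground_truth" / "breaths.csv", index=False, float_format=_FLOAT_FMT
            )

    if "correct" in stages:
        ccfg = cfg.get("correct") or {}
        if records is None:
            records = read_cohort(ccfg["cohort"])
        variables = ccfg.get(
            "variables",
            sorted({f"{o}_mass_g" for r in records for o in r.organ_masses_g}),
        )
        corrector = ccfg.get("corrector", "TL3")
        models, contexts = fit_models_and_contexts(records, variables, corrector)
        corrected = correct_cohort(records, variables, models, contexts)
        results["corrected"] = corrected
        results["models"] = models
        if out:
            corrected.to_csv(out / "corrected.csv", index=False, float_format=_FLOAT_FMT)
            with open(out / "models.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {v: dataclasses.asdict(m) for v, m in models.items()}, fh, indent=2
                )

    if "ecg" in stages:
        ecfg = cfg.get("ecg") or {}
        if not traces:
            traces = {
                Path(p).stem: read_trace(p, "ecg_voltage") for p in ecfg["traces"]
            }
        rows = []
        for name, tr in traces.items():
            if tr.signal_kind != "ecg_voltage":
                continue
            feats = analyze_ecg(tr, band_fraction=float(ecfg.get("band", 0.10)))
            rows.append({"trace": name, **dataclasses.asdict(feats)})
        results["ecg_features"] = pd.DataFrame(rows)
        if out:
            results["ecg_features"].to_csv(
                out / "ecg_features.csv", index=False, float_format=_FLOAT_FMT
            )

    if "physio" in stages:
        rows = []
        for gt in ("WT", "DMD"):
            g = grip_metrics(results["trials"][(gt, "grip")])
            cohort_df = results["cohort"]
            ta_mass = float(
                cohort_df[cohort_df.genotype == gt]["ta_mass_g"].mean()
            )
            s = stim_metrics(
                results["trials"][(gt, "force_frequency")],
                results["trials"][(gt, "fatigue")],
                ta_mass,
            )
            rows.append(
                {
                    "genotype": gt,
                    "grip_max_mn": g.max_force_mn,
                    "grip_fmi_percent": g.fmi_percent,
                    "max_tetanic_force_mn": s.max_tetanic_force_mn,
                    "specific_force_mn_per_g": s.specific_force_mn_per_g,
                    "f50_hz": s.f50_hz,
                    "fatigue_fmi_percent": s.fatigue_fmi_percent,
                }
            )
        bm = breath_metrics(traces["flow"])
        results["physio"] = pd.DataFrame(rows)
        results["breath"] = pd.DataFrame([dataclasses.asdict(bm)])
        if out:
            results["physio"].to_csv(out / "physio.csv", index=False, float_format=_FLOAT_FMT)
            results["breath"].to_csv(out / "breath.csv", index=False, float_format=_FLOAT_FMT)

    if "histo" in stages:
        rows = []
        for gt, (events, tissue, stained) in results["histo_inputs"].items():
            rows.append(
                {"section_id": gt, "metric": "pathological_index",
                 "value_percent": pathological_index(events)}
            )
            rows.append(
                {"section_id": gt, "metric": "fibrosis_fraction",
                 "value_percent": fibrosis_fraction(tissue, stained)}
            )
        results["histo"] = pd.DataFrame(rows)
        if out:
            results["histo"].to_csv(out / "histo.csv", index=False, float_format=_FLOAT_FMT)

    if "stats" in stages:
        corrected = results["corrected"]
        rows = []
        for var, sub in corrected.groupby("variable"):
            groups = {
                f"{gt}:{tp}": g["corrected"].dropna().to_numpy()
                for (gt, tp), g in sub.groupby(["genotype", "timepoint"])
            }
            groups = {k: v for k, v in groups.items() if v.size >= 3}
            if len(groups) < 2:
                continue
            for res in planned_contrasts(groups, variable=str(var)):
                rows.append(dataclasses.asdict(res))
        results["stats"] = pd.DataFrame(rows)
        if out:
            results["stats"].to_csv(out / "stats.csv", index=False, float_format=_FLOAT_FMT)

    if "report" in stages and out:
        summary = results.get("corrected")
        if summary is not None:
            summary.to_csv(out / "summary.csv", index=False, float_format=_FLOAT_FMT)
        with open(out / "log.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "package": "ratpheno",
                    "version": __version__,
                    "seed": seed,
                    "stages": stages,
                    "recipe": dataclasses.asdict(recipe) if "simulate" in stages else None,
                },
                fh,
                indent=2,
                default=str,
            )
    return results
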