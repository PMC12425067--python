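"""End-to-end pipeline: simulate (or load) → score → classify → fit → report.

A :class:`PipelineConfig` selects the stages to run and carries the scale
cutoffs, the model choices and the random seed.  All outputs are plain CSV
plus a JSON run manifest echoing the configuration, so a run is reproducible
from the manifest alone.  All randomness flows from the single seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import msm as msm_mod
from .cohort import (
    apply_inclusion,
    build_counting_process,
    collapse_to_subject,
    impute_cohort,
    read_aces,
    read_cohort,
    score_cohort,
)
from .competing import aalen_johansen_cif
from .descriptives import table_one
from .simulate import SimulationConfig, generate_cohort, write_outputs
from .survival import (
    EXPOSURE_COLUMNS,
    MODEL_COVARIATES,
    add_exposure_columns,
    fit_cox_timevarying,
    incidence_rate,
    person_years,
    schoenfeld_ph_test,
)

log = logging.getLogger("paneltrans")

ALL_STAGES = ["simulate", "score", "table1", "cox", "cif", "msm"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    outdir: str = "paneltrans_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    cohort_path: str | None = None  # load instead of simulate
    ace_path: str | None = None
    simulation: dict = field(default_factory=dict)
    depression_cutoff: int = 4
    insomnia_cutoff: int = 5
    impairment_cutoff: int = 11
    cox_model: int = 3
    exposure: str = "any"
    horizon: float = 22.0
    msm_covariate: str | None = "any_ace"
    msm_grid_step: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {unknown}")
        return cls(**data)


def _stage(name):
    log.info("[%s] starting", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Returns a dict of in-memory results keyed by stage.  Any stage error
    aborts the run with the stage named; outputs of completed stages persist.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict = {}
    manifest = {"seed": config.seed, "config": {**config.__dict__}, "stages": {}}

    stage = "simulate"
    if stage in config.stages and config.cohort_path is None:
        t0 = _stage(stage)
        sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
        cohort, aces, truth = generate_cohort(sim_cfg)
        write_outputs(cohort, aces, truth, outdir)
        results["simulate"] = (cohort, aces, truth)
        timings[stage] = time.perf_counter() - t0
    elif config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        aces = read_aces(config.ace_path)
    else:
        raise RuntimeError("stage 'simulate' skipped and no cohort_path given")

    try:
        stage = "score"
        t0 = _stage(stage)
        cohort, flow = apply_inclusion(cohort, aces)
        scored = score_cohort(
            impute_cohort(cohort),
            depression_cutoff=config.depression_cutoff,
            insomnia_cutoff=config.insomnia_cutoff,
            impairment_cutoff=config.impairment_cutoff,
        )
        intervals = add_exposure_columns(
            build_counting_process(scored, aces, horizon=config.horizon))
        subjects = collapse_to_subject(intervals)
        results["score"] = (scored, intervals, subjects)
        manifest["stages"]["score"] = {"inclusion_flow": flow,
                                       "n_participants": int(subjects.shape[0]),
                                       "n_intervals": int(intervals.shape[0])}
        timings[stage] = time.perf_counter() - t0

        if "table1" in config.stages:
            stage = "table1"
            t0 = _stage(stage)
            t1 = table_one(subjects, "any_ace")
            t1.to_csv(outdir / "table1.csv", index=False)
            results["table1"] = t1
            timings[stage] = time.perf_counter() - t0

        if "cox" in config.stages:
            stage = "cox"
            t0 = _stage(stage)
            events = int(intervals["event"].sum())
            rate, lo, hi = incidence_rate(events, person_years(intervals))
            covars = EXPOSURE_COLUMNS[config.exposure] + MODEL_COVARIATES[config.cox_model]
            fit = fit_cox_timevarying(intervals, covars, model=f"M{config.cox_model}")
            fit.summary.to_csv(outdir / "cox_model.csv", index=False)
            ph = schoenfeld_ph_test(fit, intervals, covars)
            ph.to_csv(outdir / "cox_ph_test.csv", index=False)
            results["cox"] = {"fit": fit, "incidence": (rate, lo, hi), "ph": ph}
            manifest["stages"]["cox"] = {"events": events,
                                         "incidence_rate_per_1000py": rate}
            timings[stage] = time.perf_counter() - t0

        if "cif" in config.stages:
            stage = "cif"
            t0 = _stage(stage)
            etype = np.where(subjects["event"], 1,
                             np.where(subjects["competing_death"], 2, 0))
            cif = aalen_johansen_cif(subjects["duration"], etype)
            cif.to_csv(outdir / "cif.csv", index=False)
            results["cif"] = cif
            timings[stage] = time.perf_counter() - t0

        if "msm" in config.stages:
            stage = "msm"
            t0 = _stage(stage)
            pairs = msm_mod.extract_pairs(
                scored.merge(subjects[["id", "any_ace"]], on="id"),
                covariate=config.msm_covariate)
            fit = msm_mod.fit_msm(pairs, covariate=config.msm_covariate)
            fit.intensity_table().to_csv(outdir / "msm_intensities.csv", index=False)
            if config.msm_covariate:
                msm_mod.msm_hazard_ratios(fit).to_csv(outdir / "msm_hrs.csv", index=False)
            grid = np.arange(0.0, config.horizon + 1e-9, config.msm_grid_step)
            curves = msm_mod.probability_curves(fit.q_matrix, grid)
            curves.to_csv(outdir / "msm_curves.csv", index=False)
            absorb = msm_mod.cumulative_absorption(fit.q_matrix, config.horizon)
            dur, pct = msm_mod.expected_duration(fit.q_matrix, config.horizon)
            pd.DataFrame({"state": range(1, 6), "expected_years": dur,
                          "percent_of_horizon": pct}).to_csv(
                outdir / "msm_durations.csv", index=False)
            tables = msm_mod.empirical_transition_table(scored)
            counts, pcts = tables["all"]
            pd.DataFrame(counts).to_csv(outdir / "msm_transition_counts.csv", index=False)
            results["msm"] = {"fit": fit, "absorption": absorb, "duration_pct": pct}
            manifest["stages"]["msm"] = {
                "log_likelihood": fit.log_likelihood,
                "absorption_22y": [float(x) for x in absorb],
            }
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["timings"] = timings
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
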