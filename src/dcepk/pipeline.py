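"""End-to-end orchestration: simulate -> T1 fit -> concentration -> kinetic
fit -> model selection -> cohort statistics.

Two entry points:

* :func:`analyze_study` / :func:`run_cohort_analysis` — the in-memory
  pipeline used by tests and the acceptance machinery.
* :func:`run_pipeline` — the file-based pipeline behind the CLI, writing
  every stage (NIfTI maps, CSV tables, JSON report) with provenance.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .acquisition import AcquisitionSpec
from .aif import BolusParams
from .cohort_stats import (
    PARAMS,
    StudyPair,
    anova_with_contrast,
    build_cohort_table,
    export_boxplot_data,
    group_difference_summary,
    paired_t_per_group,
)
from .concentration import dual_echo_split, signal_to_concentration
from .fileio import save_volume, write_manifest, write_provenance
from .model_selection import make_masked_maps, select_models
from .pk_models import PKFitMaps, fit_voxels
from .relaxometry import T1Map, fit_look_locker
from .synthetic import AnimalStudyPair, CohortDesign, DynamicStudy, simulate_cohort

log = logging.getLogger("dcepk")


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    alpha: float = Field(0.05, gt=0, le=1)
    kep_max: float = Field(10.0, gt=0)
    n_kep_coarse: int = Field(40, ge=5)
    n_golden: int = Field(40, ge=10)
    background_snr: float = Field(5.0, ge=0, description="baseline SNR below which a voxel is order 0")
    linearize_conversion: bool = Field(False, description="first-order small-dR1 shortcut instead of exact inversion")


class StatsOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    statistic: str = "mean"       # mean | median
    mask_rule: str = "intersection"  # test | retest | intersection
    mode: str = "absolute"        # absolute | percent


class PipelineConfig(BaseModel):
    """Validated configuration of a full run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    spec: AcquisitionSpec = AcquisitionSpec()
    design: CohortDesign = CohortDesign()
    bolus: BolusParams = BolusParams()
    fit: FitOptions = FitOptions()
    stats: StatsOptions = StatsOptions()
    seed: int = 0


@dataclass
class StudyAnalysis:
    """All derived maps of one session (flat arrays over the full grid)."""

    maps: dict[str, np.ndarray]   # masked vp/ktrans/kep/ve + model3_mask + order
    t1: T1Map
    fit: PKFitMaps | None
    analyzed_idx: np.ndarray      # indices of voxels that reached the kinetic fit


def _background_mask(study: DynamicStudy, background_snr: float) -> tuple[np.ndarray, float]:
    """Voxels whose baseline signal cannot support fitting (order 0).

    Also returns the global noise estimate (median per-voxel baseline
    temporal SD) used downstream as the echo-inversion noise tolerance.
    """
    b0, b1 = 1, study.spec.bolus_frame - 1
    base = study.echo1[:, b0:b1]
    base_mean = base.mean(axis=1)
    noise = float(np.median(base.std(axis=1, ddof=1)[base_mean > 0])) if np.any(base_mean > 0) else 0.0
    if noise <= 0:
        return base_mean <= 0, 0.0
    return base_mean < background_snr * noise, noise


def analyze_study(study: DynamicStudy, fit_opts: FitOptions | None = None) -> StudyAnalysis:
    """Run T1 fit, concentration conversion, kinetic fit and selection."""
    opts = fit_opts or FitOptions()
    n_vox = study.echo1.shape[0]
    background, noise_est = _background_mask(study, opts.background_snr)
    fg = np.nonzero(~background)[0]

    t1_fg = fit_look_locker(study.ll_pre[fg], study.spec.inversion_times_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s0, r2s = dual_echo_split(
            np.maximum(study.echo1[fg], 1e-12),
            np.maximum(study.echo2[fg], 1e-12),
            study.spec.te1_s,
            study.spec.te2_s,
            noise_sd=noise_est if noise_est > 0 else None,
        )
    conc = signal_to_concentration(s0, t1_fg, study.spec, r2star=r2s,
                                   linearize=opts.linearize_conversion)
    good = conc.valid
    idx = fg[good]

    nan = np.full(n_vox, np.nan)
    empty_maps = {k: nan.copy() for k in ("vp", "ktrans", "kep", "ve")}
    empty_maps["model3_mask"] = np.zeros(n_vox, dtype=bool)
    empty_maps["order"] = np.zeros(n_vox, dtype=int)
    t1_full = T1Map(
        t1_s=nan.copy(), t1_star_s=nan.copy(),
        residual_norm=nan.copy(), converged=np.zeros(n_vox, dtype=bool),
    )
    t1_full.t1_s[fg] = t1_fg.t1_s
    t1_full.t1_star_s[fg] = t1_fg.t1_star_s
    t1_full.residual_norm[fg] = t1_fg.residual_norm
    t1_full.converged[fg] = t1_fg.converged
    if idx.size == 0:
        return StudyAnalysis(maps=empty_maps, t1=t1_full, fit=None, analyzed_idx=idx)

    fit = fit_voxels(
        conc.ct_mM[good], study.aif,
        kep_max=opts.kep_max,
        n_kep_coarse=opts.n_kep_coarse,
        n_golden=opts.n_golden,
    )
    sel = select_models(fit, alpha=opts.alpha)
    masked = make_masked_maps(fit, sel)
    maps = empty_maps
    for key in ("vp", "ktrans", "kep", "ve"):
        maps[key][idx] = masked[key]
    maps["model3_mask"][idx] = masked["model3_mask"]
    maps["order"][idx] = masked["order"]
    return StudyAnalysis(maps=maps, t1=t1_full, fit=fit, analyzed_idx=idx)


def analyze_pair(pair: AnimalStudyPair, fit_opts: FitOptions | None = None) -> StudyPair:
    """Analyze both sessions; the analysis ROI is the tumor extent.

    In an in-vivo study the operator draws the tumor ROI on the localization
    images; for the virtual animal the generator's tumor footprint plays
    that role.
    """
    a_test = analyze_study(pair.study_test, fit_opts)
    a_retest = analyze_study(pair.study_retest, fit_opts)
    from .synthetic import ZONE_CONTRALATERAL

    return StudyPair(
        animal_id=pair.animal_id,
        group_h=pair.group_h,
        test_maps=a_test.maps,
        retest_maps=a_retest.maps,
        roi=pair.truth_test.zone > ZONE_CONTRALATERAL,
    )


@dataclass
class CohortAnalysis:
    table: pd.DataFrame
    report: dict
    pairs: list[StudyPair]


def _stats_report(table: pd.DataFrame, stats_opts: StatsOptions) -> dict:
    report: dict = {"mode": stats_opts.mode, "params": {}}
    for p in PARAMS:
        entry: dict = {}
        entry["pooled"] = group_difference_summary(table, p, stats_opts.mode).to_dict("records")
        try:
            c = anova_with_contrast(table, p, stats_opts.mode)
            entry["anova_contrast"] = {
                "F": c.f_overall, "p_overall": c.p_overall,
                "estimate": c.estimate, "se": c.se, "t": c.t, "p": c.p,
                "df_within": c.df_within,
            }
        except ValueError as exc:
            entry["anova_contrast"] = {"error": str(exc)}
        entry["paired_t"] = paired_t_per_group(table, p, stats_opts.mode).to_dict("records")
        report["params"][p] = entry
    return report


def run_cohort_analysis(
    design: CohortDesign | None = None,
    spec: AcquisitionSpec | None = None,
    bolus: BolusParams | None = None,
    seed: int | None = None,
    fit_opts: FitOptions | None = None,
    stats_opts: StatsOptions | None = None,
    cohort: list[AnimalStudyPair] | None = None,
) -> CohortAnalysis:
    """Simulate (unless given) and analyze a full cohort in memory."""
    stats_opts = stats_opts or StatsOptions()
    if cohort is None:
        cohort = simulate_cohort(design or CohortDesign(), spec, bolus=bolus, seed=seed)
    pairs = [analyze_pair(p, fit_opts) for p in cohort]
    table = build_cohort_table(pairs, stats_opts.statistic, stats_opts.mask_rule)
    return CohortAnalysis(table=table, report=_stats_report(table, stats_opts), pairs=pairs)


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

def _write_study(study: DynamicStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = study.shape
    save_volume(study.echo1, shape, out_dir / "echo1.nii.gz")
    save_volume(study.echo2, shape, out_dir / "echo2.nii.gz")
    save_volume(study.ll_pre, shape, out_dir / "ll_pre.nii.gz")
    save_volume(study.ll_post, shape, out_dir / "ll_post.nii.gz")
    save_volume(study.dwi_b0, shape, out_dir / "dwi_b0.nii.gz")
    save_volume(study.dwi_b1, shape, out_dir / "dwi_b1.nii.gz")
    study.spec.to_json(out_dir / "acquisition.json")


def _write_truth(truth, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("vp", truth.vp), ("ktrans", truth.ktrans_per_min),
        ("kep", truth.kep_per_min), ("ve", truth.ve),
        ("order", truth.order.astype(float)), ("zone", truth.zone.astype(float)),
        ("t1", truth.t1_s), ("adc", truth.adc_mm2_s),
    ):
        save_volume(arr, truth.shape, out_dir / f"{name}.nii.gz")


def _write_analysis(analysis: StudyAnalysis, shape, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(analysis.t1.t1_s, shape, out_dir / "t1.nii.gz")
    for key in ("vp", "ktrans", "kep", "ve"):
        save_volume(analysis.maps[key], shape, out_dir / f"{key}.nii.gz")
    save_volume(analysis.maps["model3_mask"].astype(float), shape, out_dir / "model3_mask.nii.gz")
    save_volume(analysis.maps["order"].astype(float), shape, out_dir / "order.nii.gz")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> CohortAnalysis:
    """Execute the full pipeline, writing every stage under ``out_dir``.

    A rerun with an identical configuration and seed is bit-identical. On a
    stage failure the partial outputs stay on disk next to an
    ``INCOMPLETE`` marker naming the failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = json.loads(config.model_dump_json())
    write_provenance(out, cfg_dict, config.seed)
    marker = out / "INCOMPLETE"
    stage = "simulate"
    try:
        marker.write_text(stage)
        t0 = time.perf_counter()
        cohort = simulate_cohort(config.design, config.spec, bolus=config.bolus, seed=config.seed)
        aif = cohort[0].study_test.aif
        aif.to_csv(out / "aif.csv")
        manifest = []
        for pair in cohort:
            for session, study, truth in (
                ("test", pair.study_test, pair.truth_test),
                ("retest", pair.study_retest, pair.truth_retest),
            ):
                sdir = out / pair.animal_id / session
                _write_study(study, sdir / "raw")
                _write_truth(truth, sdir / "truth")
                manifest.append({
                    "animal_id": pair.animal_id, "group_h": pair.group_h,
                    "session": session, "path": str(sdir),
                })
        write_manifest(manifest, out / "manifest.csv")
        log.info("simulate: %.1fs", time.perf_counter() - t0)

        stage = "analyze"
        marker.write_text(stage)
        t0 = time.perf_counter()
        pairs = []
        for pair in cohort:
            analyses = {}
            for session, study in (("test", pair.study_test), ("retest", pair.study_retest)):
                analysis = analyze_study(study, config.fit)
                analyses[session] = analysis
                _write_analysis(analysis, study.shape, out / pair.animal_id / session / "maps")
            from .synthetic import ZONE_CONTRALATERAL

            pairs.append(StudyPair(
                animal_id=pair.animal_id, group_h=pair.group_h,
                test_maps=analyses["test"].maps, retest_maps=analyses["retest"].maps,
                roi=pair.truth_test.zone > ZONE_CONTRALATERAL,
            ))
        log.info("analyze: %.1fs", time.perf_counter() - t0)

        stage = "stats"
        marker.write_text(stage)
        table = build_cohort_table(pairs, config.stats.statistic, config.stats.mask_rule)
        table.to_csv(out / "cohort_table.csv", index=False)
        report = _stats_report(table, config.stats)
        (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
        for p in PARAMS:
            export_boxplot_data(table, p, "percent").to_csv(out / f"boxplot_{p}.csv", index=False)
        marker.unlink()
        return CohortAnalysis(table=table, report=report, pairs=pairs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
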