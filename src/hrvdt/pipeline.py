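"""End-to-end pipeline: synth -> (ecg) -> hrv -> taskload -> stats.

``run_pipeline`` generates the synthetic study, extracts per-condition HRV,
performance and TLX features, runs the three-stage statistical analysis and
writes all stage artifacts (RR CSVs, the feature table, report tables) plus
a manifest with the configuration hash.  Given the same config and seed the
artifacts are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .ecg import clean_rr, ecg_to_rr
from .hrv import HRVConfig, features_as_dict, hrv_features
from .io import write_manifest, write_rr_csv, write_tlx_csv
from .synth import (AutonomicParams, BehaviorParams, EffectMap, NoiseSpec,
                    StudyDataset, StudyDesign, gen_study_dataset)
from .taskload import performance_as_dict, score_performance, score_tlx

logger = logging.getLogger(__name__)


def design_from_config(cfg: PipelineConfig) -> StudyDesign:
    s = cfg.synth
    return StudyDesign(
        n_letters=s.n_letters, n_targets=s.n_targets, n_trials=s.n_trials,
        per_trial_duration=s.per_trial_duration_s, rr_duration=s.rr_duration_s,
        base_autonomic=AutonomicParams(mean_rr=s.mean_rr_ms, a_lf=s.a_lf,
                                       a_hf=s.a_hf, f_lf=s.f_lf_hz,
                                       f_hf=s.f_hf_hz, jitter_sd=s.jitter_sd_ms),
        base_behavior=BehaviorParams(rt_median_ms=s.rt_median_ms,
                                     rt_sigma=s.rt_sigma, miss_prob=s.miss_prob,
                                     false_alarm_prob=s.false_alarm_prob),
        subject_rr_sd=s.subject_rr_sd_ms, subject_rt_sd=s.subject_rt_sd_ms,
        include_ecg=s.via_ecg, ecg_fs=s.ecg_fs_hz, ecg_noise=NoiseSpec())


def effects_from_config(cfg: PipelineConfig) -> EffectMap:
    if cfg.synth.effects == "identity":
        return EffectMap.identity()
    if cfg.synth.effects == "default":
        return EffectMap.default()
    raise ValueError(f"unknown effects map {cfg.synth.effects!r}")


def features_table(dataset: StudyDataset, cfg: PipelineConfig = PipelineConfig()
                   ) -> pd.DataFrame:
    """Subject x condition feature table: HRV + performance + TLX columns."""
    hrv_cfg = HRVConfig(ar_order=cfg.hrv.ar_order, resample_fs=cfg.hrv.resample_hz,
                        select_order_aic=cfg.hrv.select_order_aic,
                        mean_hr_instantaneous=cfg.hrv.mean_hr_instantaneous)
    rows = []
    for subj in dataset.subjects:
        for cond, data in sorted(subj.conditions.items()):
            if data.ecg is not None:
                rr = ecg_to_rr(data.ecg, cfg.ecg.median_window_ms,
                               cfg.ecg.ma_window_ms, cfg.ecg.threshold_fraction,
                               cfg.ecg.refractory_ms, clean=True,
                               window=cfg.ecg.clean_window_beats,
                               n_mad=cfg.ecg.clean_n_mad)
            else:
                rr = clean_rr(data.rr, window=cfg.ecg.clean_window_beats,
                              n_mad=cfg.ecg.clean_n_mad,
                              bounds_ms=tuple(cfg.ecg.rr_bounds_ms))
            td, fd = hrv_features(rr, hrv_cfg)
            row = {"subject": subj.subject_id, "cl_level": cond.cl_level,
                   "pl_level": cond.pl_level, "subgroup": subj.subgroup}
            row.update(features_as_dict(td, fd))
            row.update(performance_as_dict(score_performance(data.response_logs)))
            row["TLX_total"] = score_tlx(data.tlx)
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage and write artifacts; returns the output directory.

    Stage failures propagate with the stage name; the manifest is written
    last, so a partially-failed run leaves no manifest behind.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        dataset = gen_study_dataset(cfg.synth.n_subjects, effects_from_config(cfg),
                                    seed=cfg.seed, design=design_from_config(cfg))
    except Exception as exc:
        raise RuntimeError(f"synth stage failed: {exc}") from exc

    rr_dir = out / "rr"
    rr_dir.mkdir(exist_ok=True)
    for subj in dataset.subjects:
        for cond, data in sorted(subj.conditions.items()):
            write_rr_csv(data.rr, rr_dir / f"s{subj.subject_id:02d}_{cond.label}.csv")
            write_tlx_csv(data.tlx, rr_dir / f"s{subj.subject_id:02d}_{cond.label}_tlx.csv")

    try:
        table = features_table(dataset, cfg)
    except Exception as exc:
        raise RuntimeError(f"feature stage failed: {exc}") from exc
    table.to_csv(out / "features.csv", index=False, float_format="%.6f")

    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    stats_error = None
    try:
        from .stats import run_study_analysis
        report = run_study_analysis(table, holm=cfg.stats.holm)
        report.workload_performance.to_csv(report_dir / "workload_performance.csv",
                                           index=False, float_format="%.6g")
        report.hrv_by_pl.to_csv(report_dir / "hrv_by_pl.csv", index=False,
                                float_format="%.6g")
        report.correlations.to_csv(report_dir / "correlations.csv", index=False,
                                   float_format="%.6g")
        (report_dir / "README.txt").write_text(report.header + "\n", encoding="utf-8")
    except ValueError as exc:
        # small-n runs legitimately cannot support the inferential stage
        stats_error = str(exc)
        logger.warning("stats stage skipped: %s", stats_error)

    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "version": __version__, "n_subjects": cfg.synth.n_subjects,
                "stats_error": stats_error}
    write_manifest(manifest, out / "manifest.yaml")
    return out
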