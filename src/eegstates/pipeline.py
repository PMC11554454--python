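"""End-to-end pipeline: simulate -> preprocess -> segment -> parameters
-> group statistics -> response prediction.

A single YAML configuration drives every stage; all artifacts land in a
run directory together with a manifest recording the configuration,
seeds and stage outputs, so a run can be reproduced exactly from its
manifest.  Stages communicate through files (per-subject recordings,
the feature table) and can be executed individually.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_metadata, read_recording, write_recording
from .microstates import backfit, canonicalize_labels, two_level_cluster
from .montage import standard_positions
from .predict import ModelConfig, fit_predict, label_remission, rank_features
from .preprocess import standard_preprocess
from .simulate import (CohortSpec, GroundTruthSpec, GroupSpec, iter_cohort,
                       write_cohort)
from .stats import compare_cohorts, correlate_with_scores
from .temporal import cohort_feature_table, compute_metrics, \
    compute_transitions, feature_vector

log = logging.getLogger("eegstates.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "cohort": {
        "n_channels": 19,
        "sampling_rate": 250.0,
        "recording_length_s": 40.0,
        "subject_variability_cv": 0.1,
        "noise_sd": 4.0,
        "groups": [
            {"name": "HC", "n_subjects": 6,
             "hamd_baseline": [2.6, 1.0], "hamd_post": [2.6, 1.0]},
            {"name": "PSD_RP", "n_subjects": 8,
             "dwell_effect": [1.0, 1.0, 1.0, 0.8],
             "hamd_baseline": [20.0, 2.0], "hamd_post": [8.0, 3.0]},
            {"name": "PSD_NRP", "n_subjects": 6,
             "dwell_effect": [1.0, 1.0, 1.0, 0.6],
             "hamd_baseline": [20.0, 2.0], "hamd_post": [17.0, 3.0]},
        ],
    },
    "preprocess": {"low_hz": 1.0, "high_hz": 30.0},
    "segment": {"k": 4, "n_peaks": 1000, "min_peak_distance_ms": 10.0,
                "smooth_window_ms": 40.0, "shared_templates": False},
    "stats": {"group_a": "HC", "group_b_prefix": "PSD", "fdr_family": "all"},
    "predict": {"group_prefix": "PSD", "n_folds": 5, "n_rounds": 300},
}


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline configuration (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(path_or_dict)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    if "seed" not in merged or not isinstance(merged["seed"], int):
        raise ValueError("config requires an integer 'seed'")
    if not merged["cohort"].get("groups"):
        raise ValueError("config requires cohort.groups")
    return merged


def _specs_from_config(config: dict) -> tuple[GroundTruthSpec, CohortSpec]:
    c = config["cohort"]
    truth_kwargs = {k: c[k] for k in
                    ("n_channels", "sampling_rate", "gfp_envelope_sd",
                     "noise_sd", "spatial_noise_smoothness", "mean_dwell_ms",
                     "class_rate") if k in c}
    truth = GroundTruthSpec(seed=config["seed"], **truth_kwargs)
    groups = []
    for g in c["groups"]:
        kwargs = dict(g)
        for key in ("dwell_effect", "rate_effect"):
            if key in kwargs:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        for key in ("hamd_baseline", "hamd_post"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        groups.append(GroupSpec(**kwargs))
    cohort = CohortSpec(groups=groups,
                        recording_length_s=c.get("recording_length_s", 300.0),
                        subject_variability_cv=c.get("subject_variability_cv", 0.1),
                        seed=config["seed"])
    return truth, cohort


def stage_simulate(config: dict, run_dir: Path) -> Path:
    truth, cohort = _specs_from_config(config)
    records = list(iter_cohort(cohort, truth, render=True))
    out = write_cohort(records, run_dir / "cohort", truth=truth)
    log.info("simulated %d subjects into %s", len(records), out)
    return out


def stage_preprocess(config: dict, run_dir: Path) -> Path:
    p = config["preprocess"]
    src = run_dir / "cohort"
    dst = run_dir / "preprocessed"
    dst.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(src / "metadata.csv")
    for subject_id in meta["subject_id"]:
        rec = read_recording(src / f"{subject_id}.csv")
        rec.positions = standard_positions(rec.ch_names)
        clean = standard_preprocess(rec, p["low_hz"], p["high_hz"])
        write_recording(clean, dst / f"{subject_id}.csv")
    meta.to_csv(dst / "metadata.csv", index=False)
    log.info("preprocessed %d recordings", len(meta))
    return dst


def _group_of(meta: pd.DataFrame, subject_id: str) -> str:
    return str(meta.set_index("subject_id").loc[subject_id, "group"])


def stage_segment(config: dict, run_dir: Path) -> Path:
    s = config["segment"]
    src = run_dir / "preprocessed"
    if not src.exists():
        src = run_dir / "cohort"
    dst = run_dir / "segmentation"
    dst.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(src / "metadata.csv")

    if s.get("shared_templates", False):
        partitions = {"all": list(meta["subject_id"])}
    else:
        partitions = {g: list(sub["subject_id"])
                      for g, sub in meta.groupby("group")}

    labels_dir = dst / "labels"
    labels_dir.mkdir(exist_ok=True)
    template_rows = []
    for part, subjects in sorted(partitions.items()):
        def _iter():
            for sid in subjects:
                yield sid, read_recording(src / f"{sid}.csv")
        group_templates, _ = two_level_cluster(
            _iter(), k=s["k"], n_peaks=s["n_peaks"],
            min_peak_distance_ms=s["min_peak_distance_ms"],
            seed=config["seed"])
        positions = standard_positions(group_templates.ch_names)
        group_templates = canonicalize_labels(group_templates, positions)
        for label, row in zip(group_templates.labels, group_templates.maps):
            template_rows.append({"partition": part, "class": label,
                                  **dict(zip(group_templates.ch_names, row))})
        for sid in subjects:
            rec = read_recording(src / f"{sid}.csv")
            seg = backfit(rec, group_templates,
                          smooth_window_ms=s.get("smooth_window_ms", 0.0))
            np.savetxt(labels_dir / f"{sid}.csv", seg.labels, fmt="%d",
                       header=f"gev={seg.gev:.6f}", comments="# ")
    pd.DataFrame(template_rows).to_csv(dst / "templates.csv", index=False)
    meta.to_csv(dst / "metadata.csv", index=False)
    log.info("segmented %d subjects in %d partition(s)", len(meta), len(partitions))
    return dst


def stage_params(config: dict, run_dir: Path) -> Path:
    src = run_dir / "segmentation"
    meta = read_metadata(src / "metadata.csv")
    rate = config["cohort"]["sampling_rate"]
    feats = {}
    for sid in meta["subject_id"]:
        labels = np.loadtxt(src / "labels" / f"{sid}.csv", dtype=int)
        feats[sid] = feature_vector(compute_metrics(labels, rate),
                                    compute_transitions(labels))
    table = cohort_feature_table(feats, meta)
    out = run_dir / "features.csv"
    table.to_csv(out, index=False)
    log.info("wrote feature table %s (%d subjects)", out, len(table))
    return out


def stage_stats(config: dict, run_dir: Path) -> Path:
    st = config["stats"]
    table = pd.read_csv(run_dir / "features.csv")
    group_a = table[table["group"] == st["group_a"]]
    group_b = table[table["group"].str.startswith(st["group_b_prefix"])]
    comparison = compare_cohorts(group_a, group_b, fdr_family=st["fdr_family"])
    out = run_dir / "comparison.csv"
    comparison.to_csv(out, index=False)
    correlation = correlate_with_scores(group_b, group_b["hamd_baseline"])
    correlation.to_csv(run_dir / "correlation.csv", index=False)
    log.info("group comparison written to %s (%d significant)",
             out, int(comparison["significant"].sum()))
    return out


def stage_predict(config: dict, run_dir: Path) -> Path:
    pr = config["predict"]
    table = pd.read_csv(run_dir / "features.csv")
    patients = table[table["group"].str.startswith(pr["group_prefix"])]
    outcomes = [label_remission(b, p) for b, p in
                zip(patients["hamd_baseline"], patients["hamd_post"])]
    y = np.array([o.remission for o in outcomes], dtype=int)
    model_cfg = ModelConfig(seed=config["seed"],
                            n_folds=pr.get("n_folds", 5),
                            n_rounds=pr.get("n_rounds", 500))
    result = fit_predict(patients, y, model_cfg)
    report = {
        "n_subjects": int(len(patients)),
        "n_remitters": int(y.sum()),
        "auc": result.pooled.auc,
        "accuracy": result.pooled.accuracy,
        "sensitivity": result.pooled.sensitivity,
        "specificity": result.pooled.specificity,
        "f1": result.pooled.f1,
        "per_fold_auc": [f.auc for f in result.per_fold],
    }
    out = run_dir / "prediction.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    rank_features(result).to_csv(run_dir / "importance.csv", index=False)
    log.info("prediction report written to %s (pooled AUC %.3f)",
             out, result.pooled.auc)
    return out


_STAGES = [("simulate", stage_simulate), ("preprocess", stage_preprocess),
           ("segment", stage_segment), ("params", stage_params),
           ("stats", stage_stats), ("predict", stage_predict)]


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run every stage into ``out_dir`` and write a manifest; returns the dir."""
    config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, "seed": config["seed"],
                "config": config, "stages": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    start = time.time()
    for name, stage in _STAGES:
        t0 = time.time()
        try:
            out = stage(config, run_dir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        manifest["stages"][name] = {"output": str(out),
                                    "seconds": round(time.time() - t0, 3)}
    manifest["total_seconds"] = round(time.time() - start, 3)
    with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline complete in %.1fs: %s", manifest["total_seconds"], run_dir)
    return run_dir
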