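"""End-to-end orchestration: simulate -> extract -> preprocess -> evaluate.

A run is driven by a :class:`RunConfig` (loadable from YAML with full
defaulting), executes the four stages in order, and leaves a run directory
containing features.csv, scores.csv, pca_model.json, the metrics tables,
the p-value matrices and a JSON manifest (seed, config hash, stage
timings) from which the whole run is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as mdl
from .features import (
    FEATURE_COLUMNS,
    extract_feature_table,
    extract_from_directory,
    write_feature_table,
)
from .preprocess import build_table, preprocess_pipeline, save_pca_model
from .recording import VOWELS, read_wav
from .synth import CohortSpec, generate_cohort, write_metadata

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults mirror the analysis defaults."""

    out_dir: str = "run"
    audio_dir: str | None = None      # None -> simulate a cohort instead
    metadata_path: str | None = None
    seed: int = 0
    # cohort (simulation runs)
    n_control: int = 18
    n_bulbar: int = 14
    n_nonbulbar: int = 31
    duration_s: float = 3.0
    sample_rate_hz: float = 44100.0
    # preprocessing
    n_pcs: int = 8
    subject_level: bool = False
    # evaluation
    cv_folds: int = 10
    cv_trials: int = 10
    thresholds: tuple[float, ...] = (0.50, 0.95)
    model_names: tuple[str, ...] = mdl.MODEL_NAMES
    comparison_names: tuple[str, ...] = mdl.COMPARISON_NAMES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("thresholds", "model_names", "comparison_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_control=self.n_control, n_bulbar=self.n_bulbar,
            n_nonbulbar=self.n_nonbulbar, duration_s=self.duration_s,
            sample_rate_hz=self.sample_rate_hz, seed=self.seed)

    def digest(self) -> str:
        return mdl.config_digest({k: str(v) for k, v in asdict(self).items()})


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(audio_dir: str | Path, metadata: pd.DataFrame) -> ValidationReport:
    """Check WAV readability, mono channel and metadata completeness."""
    report = ValidationReport()
    audio_dir = Path(audio_dir)
    required = {"subject_id", "sex", "age", "group"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        report.fatal.append(f"metadata missing columns: {sorted(missing_cols)}")
        return report
    meta = metadata.set_index("subject_id")
    if meta["age"].isna().any():
        bad = meta.index[meta["age"].isna()].tolist()
        report.fatal.append(f"missing age (age correction impossible): {bad}")
    bad_group = meta.index[~meta["group"].isin(("C", "B", "NB"))].tolist()
    if bad_group:
        report.fatal.append(f"unknown group labels for subjects: {bad_group}")
    bad_sex = meta.index[~meta["sex"].isin(("male", "female"))].tolist()
    if bad_sex:
        report.fatal.append(f"unknown sex labels for subjects: {bad_sex}")
    wavs = sorted(audio_dir.glob("*.wav"))
    if not wavs:
        report.fatal.append(f"no WAV files under {audio_dir}")
    for path in wavs:
        subject_id, _, vowel = path.stem.rpartition("_")
        if vowel not in VOWELS:
            report.fatal.append(f"{path.name}: unknown vowel label {vowel!r}")
        if subject_id not in meta.index:
            report.fatal.append(f"{path.name}: subject {subject_id!r} not in metadata")
        try:
            read_wav(path)
        except Exception as exc:  # unreadable or non-mono
            report.fatal.append(f"{path.name}: {exc}")
    return report


def run_full(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages are idempotent: an existing features.csv / scores.csv in the
    run directory is reused instead of recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config),
                      "config_hash": config.digest(), "timings_s": {}}

    t0 = time.time()
    features_path = out / "features.csv"
    if features_path.exists():
        logger.info("reusing cached %s", features_path)
        table = pd.read_csv(features_path)
    else:
        if config.audio_dir is None:
            logger.info("simulating cohort (seed=%d)", config.seed)
            recordings, subjects = generate_cohort(config.cohort_spec())
            write_metadata(subjects, out / "metadata.csv")
            feature_rows = extract_feature_table(recordings)
            table = build_table(feature_rows.drop(columns=["sex", "age_years", "group"]),
                                subjects)
        else:
            if config.metadata_path is None:
                raise ValueError("audio_dir given but metadata_path missing")
            metadata = pd.read_csv(config.metadata_path)
            report = validate_inputs(config.audio_dir, metadata)
            if not report.ok:
                raise ValueError("input validation failed: " + "; ".join(report.fatal))
            feature_rows = extract_from_directory(config.audio_dir, metadata)
            table = build_table(feature_rows.drop(columns=["sex", "age_years", "group"]),
                                metadata)
        write_feature_table(table, features_path)
    manifest["timings_s"]["extract"] = round(time.time() - t0, 2)

    t0 = time.time()
    scores_path = out / "scores.csv"
    pre = preprocess_pipeline(table, n_pcs=config.n_pcs,
                              subject_level=config.subject_level)
    pre.selected.to_csv(scores_path, index=False)
    save_pca_model(pre.pca, pre.params, pre.age_model, out / "pca_model.json")
    manifest["cumulative_variance_at_k"] = float(pre.pca.cumulative_variance[config.n_pcs - 1])
    manifest["timings_s"]["preprocess"] = round(time.time() - t0, 2)

    t0 = time.time()
    scheme = mdl.CVScheme(k=config.cv_folds, trials=config.cv_trials, seed=config.seed)
    grid = mdl.evaluate_grid(pre.selected, config.model_names,
                             config.comparison_names, scheme, config.thresholds)
    tables = mdl.results_report(grid, seed=config.seed, n_pcs=config.n_pcs,
                                config_hash=config.digest(),
                                model_names=config.model_names,
                                comparison_names=config.comparison_names,
                                thresholds=config.thresholds)
    for thr, tbl in tables.items():
        tbl.to_csv(out / f"metrics_threshold_{int(thr * 100)}.csv", index=False)
    (out / "metrics.txt").write_text(
        mdl.report_text(tables, config.seed, config.n_pcs, config.digest()))
    pvals = []
    for cname in config.comparison_names:
        for thr in config.thresholds:
            acc = {m: grid[(cname, m, thr)].fold_accuracy for m in config.model_names}
            tbl = mdl.compare_models(acc)
            tbl.insert(0, "comparison", cname)
            tbl.insert(1, "threshold", thr)
            pvals.append(tbl)
    pd.concat(pvals, ignore_index=True).to_csv(out / "model_comparisons.csv", index=False)
    manifest["timings_s"]["evaluate"] = round(time.time() - t0, 2)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return out
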