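"""End-to-end orchestration: simulate -> features -> outcomes -> diagnostics
-> model search -> external validation, with a reproducible run manifest.

A run is configured by a plain dict (usually loaded from YAML).  Required
keys: ``seed``, ``out_dir``, ``experiment`` (MEP or LMFP) and ``design``
(cross_session or cross_cohort).  Optional keys override the synthetic
cohort parameters, the feature battery subset, the categorization windows
and the search registries.  Every random draw flows from the single master
seed via named substreams; re-running a manifest reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from neuromodml import __version__
from neuromodml.complexity import complexity_battery, default_battery
from neuromodml.errors import ConfigurationError
from neuromodml.models import feature_set_universe, run_experiment
from neuromodml.outcomes import baseline_tms_features, derive_labels, make_methods
from neuromodml.reliability import PairedVisitTable, drift_report
from neuromodml.spectral import DEFAULT_BANDS, band_power_table
from neuromodml.synthetic import CohortSpec, generate_cohorts, save_cohort, small_spec

REQUIRED_KEYS = ("seed", "out_dir", "experiment", "design")


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    digests: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config, "version": self.version, "seed": self.seed,
            "digests": self.digests, "timings_s": self.timings_s,
        }, indent=2, default=str)


def validate_config(config: dict) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigurationError(f"config missing required keys: {missing}")
    if config["experiment"] not in ("MEP", "LMFP"):
        raise ConfigurationError("experiment must be 'MEP' or 'LMFP'")
    if config["design"] not in ("cross_session", "cross_cohort"):
        raise ConfigurationError("design must be 'cross_session' or 'cross_cohort'")


def build_spec(config: dict) -> CohortSpec:
    overrides = dict(config.get("cohort", {}))
    overrides.setdefault("seed", config["seed"])
    if config.get("full_scale", False):
        return CohortSpec(**overrides)
    return small_spec(**overrides)


def select_measures(names=None) -> tuple:
    battery = default_battery()
    if names is None:
        return battery
    by_name = {s.name: s for s in battery}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise ConfigurationError(f"unknown complexity measures: {unknown}")
    return tuple(by_name[n] for n in names)


def extract_features(sessions, experiment: str, bands=DEFAULT_BANDS,
                     measures=None, complexity_channels=None) -> pd.DataFrame:
    """Sessions x (metadata + spectral + complexity + pre-TBS features).

    ``complexity_channels`` restricts the (expensive) complexity battery to
    a channel subset; band powers are always computed on every channel.
    """
    rows = {}
    for s in sessions:
        row = pd.concat([band_power_table(s.rseeg, bands),
                         complexity_battery(s.rseeg, measures,
                                            channels=complexity_channels)])
        for k, v in baseline_tms_features(s, experiment).items():
            row[k] = v
        row["participant"] = s.participant_id
        row["cohort"] = s.cohort_id
        row["visit"] = s.visit
        rows[s.session_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "session_id"
    return df


def outcome_tables(sessions, methods) -> tuple:
    """(labels, statistics) DataFrames: sessions x method ids."""
    lab_rows, stat_rows = {}, {}
    for s in sessions:
        labels = derive_labels(s, methods)
        lab_rows[s.session_id] = {l.method_id: l.label for l in labels}
        stat_rows[s.session_id] = {l.method_id: l.statistic for l in labels}
    labels = pd.DataFrame.from_dict(lab_rows, orient="index")
    stats_ = pd.DataFrame.from_dict(stat_rows, orient="index")
    labels.index.name = stats_.index.name = "session_id"
    return labels, stats_


def _paired_tables(df: pd.DataFrame, meta: pd.DataFrame, columns) -> list:
    """Participant-indexed initial/retest tables for each column."""
    out = []
    joined = df.join(meta[["participant", "cohort", "visit"]], how="inner") \
        if not set(("participant", "visit")).issubset(df.columns) else df
    joined = joined.assign(pkey=joined["cohort"].astype(str) + "_"
                           + joined["participant"].astype(str))
    for col in columns:
        piv = joined.pivot_table(index="pkey", columns="visit", values=col,
                                 aggfunc="first")
        init = piv["initial"] if "initial" in piv else pd.Series(dtype=float)
        ret = piv["retest"] if "retest" in piv else pd.Series(dtype=float)
        out.append(PairedVisitTable(col, init, ret))
    return out


def diagnose(feature_table: pd.DataFrame, labels: pd.DataFrame,
             stats_: pd.DataFrame, alpha: float = 0.05):
    """Shift and reliability diagnostics over the assembled tables."""
    meta = feature_table[["participant", "cohort", "visit"]]
    feat_cols = [c for c in feature_table.columns
                 if c.startswith(("pow_", "cx_", "pre_"))]
    features = _paired_tables(feature_table, meta, feat_cols)
    label_tables = _paired_tables(labels.join(meta), meta, list(labels.columns))
    stat_tables = _paired_tables(stats_.join(meta), meta, list(stats_.columns))
    return drift_report(features, label_tables, stat_tables, alpha=alpha)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> tuple:
    """Execute all stages; returns (RunManifest, outputs dict)."""
    validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(config=dict(config), version=__version__, seed=seed)
    outputs = {}

    def timed(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        return result

    spec = build_spec(config)
    sessions = timed("simulate", lambda: generate_cohorts(spec))
    outputs["sessions"] = sessions
    if config.get("write_sessions", False):
        timed("write_sessions", lambda: save_cohort(sessions, out_dir / "sessions"))

    feat_cfg = config.get("features", {})
    measures = select_measures(feat_cfg.get("measures"))
    features = timed("extract", lambda: extract_features(
        sessions, config["experiment"], measures=measures,
        complexity_channels=feat_cfg.get("channels")))
    outputs["features"] = features
    fpath = out_dir / "features.csv"
    features.to_csv(fpath)
    manifest.digests["features.csv"] = _sha256(fpath)

    windows = config.get("windows")
    methods = make_methods(config["experiment"],
                           windows=[tuple(w) for w in windows] if windows else None)
    labels, stats_ = timed("outcomes", lambda: outcome_tables(sessions, methods))
    outputs["labels"], outputs["stats"] = labels, stats_
    for name, df in (("labels.csv", labels), ("stats.csv", stats_)):
        p = out_dir / name
        df.to_csv(p)
        manifest.digests[name] = _sha256(p)

    report = timed("diagnose", lambda: diagnose(features, labels, stats_))
    outputs["drift"] = report
    (out_dir / "drift.json").write_text(report.to_json())
    (out_dir / "drift.txt").write_text(report.summary() + "\n")
    manifest.digests["drift.json"] = _sha256(out_dir / "drift.json")

    search_cfg = dict(config.get("search", {}))
    if "feature_sets" not in search_cfg:
        band_names = [b.name for b in DEFAULT_BANDS]
        search_cfg["feature_sets"] = feature_set_universe(
            band_names, [m.name for m in measures])
    if "methods" not in search_cfg:
        search_cfg["methods"] = [m.method_id for m in methods]
    experiment_report = timed("search", lambda: run_experiment(
        config["design"], features, labels, search_cfg, seed))
    outputs["experiment"] = experiment_report

    lpath = out_dir / "leaderboard.csv"
    experiment_report.leaderboard.to_csv(lpath, index=False)
    manifest.digests["leaderboard.csv"] = _sha256(lpath)
    selected = {
        "selected": experiment_report.selected.model_id
        if experiment_report.selected else None,
        "cv_mean": experiment_report.selected_cv.mean.to_dict()
        if experiment_report.selected_cv is not None else None,
        "validation_point": experiment_report.validation.point.to_dict()
        if experiment_report.validation is not None else None,
        "validation_ci": {
            m: [experiment_report.validation.ci_low[m],
                experiment_report.validation.ci_high[m]]
            for m in experiment_report.validation.point.index}
        if experiment_report.validation is not None else None,
        "n_train": experiment_report.n_train,
        "n_val": experiment_report.n_val,
    }
    (out_dir / "selected_model.json").write_text(
        json.dumps(selected, indent=2, default=float))
    manifest.digests["selected_model.json"] = _sha256(out_dir / "selected_model.json")

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest, outputs
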