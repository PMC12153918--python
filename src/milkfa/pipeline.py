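"""End-to-end orchestration: simulate/ingest -> clean -> PCA/GH -> subsample
-> cluster -> classify -> transitions -> interpret.

A single :class:`RunConfig` drives the whole run.  Every stage writes its
table under the output directory and the manifest records parameters, row
counts and content hashes, so identical configs and seeds produce
identical manifests.  A second ("projected") population can be scored with
the frozen reference models — the reference population fits the PCA, the
clustering and the classifier; the projected population only passes
through them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .classify import TunedRandomForestClassifier, cross_validate, predict_membership
from .cluster import WardClusterer
from .dynamics import transition_matrix
from .interpret import flag_records, summarize_clusters
from .preprocess import ReferenceProjection, clean_records, compute_gh, convert_to_fat_basis, project
from .reference import FA_TRAITS
from .subsample import StrataPlan, stratified_subsample
from .synthetic import SimConfig, default_state_models, inject_artifacts, simulate_population

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "simulate",
    "clean",
    "convert",
    "score_gh",
    "subsample",
    "cluster",
    "classify",
    "transitions",
    "interpret",
)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    outdir: str = "milkfa_run"
    input_mode: str = "synthetic"  # "synthetic" | "csv"
    input_csv: str | None = None
    seed: int = 0
    # synthetic-population settings
    n_herds: int = 60
    horizon_days: int = 180
    within_state_sd_fraction: float = 0.5
    artifact_rates: dict = field(
        default_factory=lambda: {"out_of_range": 0.01, "negative_fa": 0.01, "missing": 0.01}
    )
    # preprocessing / subsampling / clustering / classification
    variance_threshold: float = 0.95
    strata_per_n: int = 400
    k: int | None = None
    k_min: int = 2
    k_max: int = 15
    rf_trees: int = 100
    cv_folds: int = 10
    flag_map: dict = field(default_factory=lambda: dict(reference.DEFAULT_FLAG_MAP))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.flag_map = {int(k): v for k, v in cfg.flag_map.items()}
        return cfg


def _write(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, index=True)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return {"path": path.name, "rows": int(len(df)), "sha256": digest}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record_stage(name: str, **tables: pd.DataFrame) -> None:
        manifest["stages"][name] = {
            key: _write(df, out / f"{name}_{key}.csv") for key, df in tables.items()
        }

    # -- simulate / ingest --------------------------------------------------
    if config.input_mode == "synthetic":
        states = default_state_models(config.within_state_sd_fraction)
        sim = SimConfig(
            n_herds=config.n_herds,
            horizon_days=config.horizon_days,
            seed=config.seed,
        )
        records, truth = simulate_population(states, sim)
        records, artifact_log = inject_artifacts(
            records, config.artifact_rates, seed=config.seed + 1
        )
        record_stage("simulate", records=records, truth=truth, artifacts=artifact_log)
    elif config.input_mode == "csv":
        if not config.input_csv:
            raise ValueError("input_mode 'csv' requires input_csv")
        records = pd.read_csv(config.input_csv, parse_dates=["date"])
        missing = [t for t in FA_TRAITS if t not in records.columns]
        if missing:
            raise ValueError(f"input csv is missing FA columns: {missing}")
        if "unit_basis" not in records.columns:
            records["unit_basis"] = "milk_basis"
        record_stage("simulate", records=records)
    else:
        raise ValueError(f"unknown input_mode {config.input_mode!r}")

    # -- clean + convert ----------------------------------------------------
    kept, rejection_log = clean_records(records)
    if len(kept) + len(rejection_log) != len(records):
        raise AssertionError("cleaning ledger not conserved")
    record_stage("clean", kept=kept, rejected=rejection_log)
    fat_basis = convert_to_fat_basis(kept)
    record_stage("convert", records=fat_basis)

    # -- reference PCA + GH -------------------------------------------------
    projection = ReferenceProjection(variance_threshold=config.variance_threshold)
    projection.fit(fat_basis)
    projection.save(out / "reference_projection.json")
    scores = project(fat_basis, projection)
    gh = compute_gh(scores, projection)
    gh_table = scores.assign(gh=gh)
    record_stage("score_gh", scores=gh_table)

    # -- stratified subsample ----------------------------------------------
    plan = StrataPlan(per_stratum_n=config.strata_per_n, seed=config.seed + 2)
    keys, report = stratified_subsample(gh, plan)
    (out / "subsample_report.json").write_text(json.dumps(report, indent=2))
    record_stage("subsample", keys=pd.DataFrame({"key": keys}))

    # -- cluster ------------------------------------------------------------
    subset = fat_basis.loc[keys]
    clusterer = WardClusterer(k=config.k, k_min=config.k_min, k_max=config.k_max)
    clusterer.fit(subset[list(FA_TRAITS)].to_numpy())
    linkage_df = pd.DataFrame(
        clusterer.linkage_, columns=["left", "right", "height", "size"]
    )
    labels_df = pd.DataFrame({"key": keys, "label": clusterer.labels_})
    record_stage("cluster", linkage=linkage_df, labels=labels_df)
    manifest["stages"]["cluster"]["k"] = int(clusterer.k_)

    # -- classify (random forest on the FA traits) --------------------------
    rf = TunedRandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features_grid=("sqrt",),
        random_state=config.seed + 3,
    )
    sub_x = subset[list(FA_TRAITS)].to_numpy()
    cm, fold_metrics = cross_validate(
        sub_x, clusterer.labels_, rf, folds=config.cv_folds, seed=config.seed + 3
    )
    rf.fit(sub_x, clusterer.labels_)
    proba, hard = predict_membership(rf, fat_basis[list(FA_TRAITS)])
    predictions = pd.concat(
        [fat_basis[["herd_id", "date"]], proba], axis=1
    ).assign(label=hard)
    record_stage(
        "classify", confusion=cm, fold_metrics=fold_metrics, predictions=predictions
    )

    # -- transitions --------------------------------------------------------
    tm = transition_matrix(
        predictions[["herd_id", "date", "label"]], n_states=int(clusterer.k_)
    )
    record_stage("transitions", counts=tm.counts, percent=tm.to_percent())

    # -- interpret ----------------------------------------------------------
    summary = summarize_clusters(
        fat_basis.drop(columns=["unit_basis"]), predictions["label"]
    )
    flag_map = {c: config.flag_map.get(c, "green") for c in range(1, clusterer.k_ + 1)}
    flags = flag_records(predictions["label"].to_numpy(), flag_map=flag_map)
    alert_series = predictions.assign(flag=flags.to_numpy())
    record_stage(
        "interpret",
        cluster_means=summary.means,
        cluster_sds=summary.sds,
        alerts=alert_series,
    )

    manifest_json = json.dumps(manifest, indent=2, default=str)
    (out / "manifest.json").write_text(manifest_json)
    return manifest
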