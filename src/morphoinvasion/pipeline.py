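"""End-to-end pipeline: simulate -> features -> motility -> summarize ->
classify -> PLS, with a provenance manifest.

The pipeline is a thin orchestration layer over the library modules. Given a
config (YAML mapping or dict) it executes the requested stages in dependency
order, writes fixed-schema CSV/JSON outputs under the configured output
directory and records a manifest with the seed, stage timings and SHA-256
hashes of every written file. Reruns with the same config and seed reproduce
byte-identical numeric payloads.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header, floats
with 9 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, condition_stats, motility, pls, synthetic
from .morphometry import FEATURE_NAMES, profile_table

logger = logging.getLogger("morphoinvasion.pipeline")

STAGES = ("simulate", "features", "motility", "summarize", "classify", "pls")
FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    study: str = "default"            # "default" | "recovery"
    n_cells: int = 60
    n_conditions: int = 8             # recovery study only
    speed_threshold: float = classification.SPEED_THRESHOLD
    invasion_threshold: float = classification.INVASION_THRESHOLD_MESENCHYMAL
    classifier_rates: tuple[float, ...] = (1.0,)
    classifier_estimators: tuple[int, ...] = (50,)
    pls_components: int | str = "auto"
    pls_n_perm: int = 200
    pls_responses: tuple[str, ...] = ("speed", "persistence", "invasion")

    @classmethod
    def from_mapping(cls, cfg: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(cfg)
        if "outdir" not in cfg:
            raise ValueError("config must set 'outdir'")
        cfg["outdir"] = Path(cfg["outdir"])
        for key in ("stages", "classifier_rates", "classifier_estimators", "pls_responses"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the provenance manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "files": {},
        "config": {k: str(v) for k, v in vars(config).items()},
    }
    state: dict = {}
    order = [s for s in STAGES if s in config.stages]
    for stage in order:
        t0 = time.perf_counter()
        logger.info("[%s] starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"status": "ok", "seconds": round(dt, 3)}
        logger.info("[%s] done in %.1fs", stage, dt)
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> None:
    if config.study == "default":
        specs = synthetic.default_study_specs(config.seed, n_cells=config.n_cells)
    elif config.study == "recovery":
        specs = synthetic.recovery_study_specs(
            config.seed, n_conditions=config.n_conditions, n_cells=config.n_cells
        )
    else:
        raise ValueError(f"unknown study {config.study!r}")
    study = synthetic.generate_study(specs)
    synthetic.write_study(study, out / "study")
    state["study"] = study


def _require(state: dict, key: str, needed_by: str):
    if key not in state:
        raise ValueError(f"stage {needed_by!r} needs missing input {key!r}; "
                         f"run its upstream stage first")
    return state[key]


def _stage_features(config: PipelineConfig, out: Path, state: dict) -> None:
    study: synthetic.SyntheticStudy = _require(state, "study", "features")
    tables = [
        profile_table(masks, condition=name,
                      mask_ids=[f"{name}_{i:03d}" for i in range(len(masks))])
        for name, masks in study.masks.items()
    ]
    features = pd.concat(tables, ignore_index=True)
    _write_csv(features, out / "features.csv")
    state["features"] = features


def _stage_motility(config: PipelineConfig, out: Path, state: dict) -> None:
    study: synthetic.SyntheticStudy = _require(state, "study", "motility")
    metrics = motility.metrics_table(study.trajectories)
    spheroids = motility.spheroid_table(study.spheroids)
    _write_csv(metrics, out / "metrics.csv")
    _write_csv(spheroids, out / "spheroid_folds.csv")
    state["metrics"] = metrics
    state["spheroids"] = spheroids


def _stage_summarize(config: PipelineConfig, out: Path, state: dict) -> None:
    lines = None
    if "study" in state:
        lines = {c.name: c.cell_line for c in state["study"].conditions}
    summaries = condition_stats.summarize(
        _require(state, "features", "summarize"),
        _require(state, "metrics", "summarize"),
        _require(state, "spheroids", "summarize"),
        cell_lines=lines,
    )
    frame = condition_stats.summary_frame(summaries)
    frame.index.name = "condition"
    frame.reset_index().to_csv(out / "summaries.csv", index=False, float_format=FLOAT_FMT)
    state["summaries"] = summaries
    state["summary_frame"] = frame


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> None:
    features = _require(state, "features", "classify")
    summaries = _require(state, "summaries", "classify")
    report: dict = {}
    for response, thr in (
        ("speed", config.speed_threshold),
        ("invasion", config.invasion_threshold),
    ):
        labeling = classification.label_conditions(summaries, response, thr)
        if len(set(labeling.labels.values())) < 2:
            report[response] = {"labels": labeling.labels,
                                "note": "single-class labeling; classifiers skipped"}
            continue
        ranking = classification.rank_single_features(features, labeling)
        groups = classification.evaluate_feature_groups(features, labeling)
        grid = classification.grid_search(
            features, labeling,
            rates=config.classifier_rates,
            estimator_counts=config.classifier_estimators,
        )
        report[response] = {
            "threshold": thr,
            "labels": labeling.labels,
            "single_feature_ranking": ranking.to_dict("records"),
            "feature_groups": [
                {"feature_set": g.feature_set, "auroc_train": g.auroc_train,
                 "auroc_cv": g.auroc_cv, "n_cells": g.n_cells}
                for g in groups
            ],
            "grid_search": grid.to_dict("records"),
        }
    with open(out / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    state["classification"] = report


def _stage_pls(config: PipelineConfig, out: Path, state: dict) -> None:
    frame: pd.DataFrame = _require(state, "summary_frame", "pls")
    X = frame[list(FEATURE_NAMES)]
    Y = frame[list(config.pls_responses)]
    A_max = min(len(X) - 2, X.shape[1])
    q2 = pls.q2_loocv(X, Y, A_max)
    r2 = pls.r2_per_component(X, Y, A_max)
    diag = pls.Diagnostics(R2_per_A=r2[: len(q2)], Q2_per_A=q2)
    if config.pls_components == "auto":
        A = pls.choose_components(diag)
    else:
        A = int(config.pls_components)
    model = pls.fit_pls(X, Y, A)
    perm = pls.permutation_test(X, Y, A, n_perm=config.pls_n_perm, seed=config.seed)
    vip_overall = pls.vip_scores(model)
    report = {
        "A": A,
        "R2_per_A": diag.R2_per_A.tolist(),
        "Q2_per_A": diag.Q2_per_A.tolist(),
        "permutation": {"observed_q2": perm.observed_q2, "p_value": perm.p_value,
                        "n_perm": len(perm.null_q2)},
        "vip_overall": vip_overall.to_dict(),
        "vip_per_response": {
            resp: pls.vip_scores(model, response=resp).to_dict()
            for resp in model.y_columns
        },
        "scores": {str(c): model.T[i].tolist() for i, c in enumerate(model.X_train.index)},
    }
    with open(out / "pls.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    state["pls"] = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "motility": _stage_motility,
    "summarize": _stage_summarize,
    "classify": _stage_classify,
    "pls": _stage_pls,
}


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.WARNING if quiet else logging.INFO
    logging.basicConfig(
        stream=sys.stderr, level=level,
        format="%(name)s %(levelname)s %(message)s", force=True,
    )
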