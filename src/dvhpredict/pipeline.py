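"""End-to-end orchestration: simulate → filter → regress → train → evaluate → audit.

Every stage writes a plain CSV/JSON artifact into the run directory so that
any stage can also be run standalone; a manifest records package/library
versions, the configuration, derived stage seeds and a SHA-256 checksum of
every artifact, making a rerun with the same configuration verifiable.
One global seed deterministically derives all stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dvhpredict
from dvhpredict.audit import PlanDoseSummary, audit, audit_frame
from dvhpredict.evaluation import run_cv
from dvhpredict.ga import GAConfig, ga_bp_train
from dvhpredict.network import NetworkParams, TrainConfig, predict, save_model, train
from dvhpredict.preprocessing import apply_scaler, fit_scaler, mahalanobis_filter
from dvhpredict.regression import association_frame, association_table
from dvhpredict.synthetic import (
    OUTPUT_NAMES,
    CohortSpec,
    cohort_to_frame,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "filter", "regress", "train", "evaluate", "audit")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    models: tuple[str, ...] = ("bp", "ga-bp")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    alpha: float = 0.05
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    ga_cfg: GAConfig = field(default_factory=GAConfig)
    cv_k: int = 5
    cv_repeats: int = 5
    audit_margin: float = 5.0

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for m in self.models:
            if m not in ("bp", "ga-bp"):
                raise ValueError(f"unknown model kind {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "seed" in doc:
            cfg.seed = int(doc["seed"])
        if "stages" in doc:
            cfg.stages = tuple(doc["stages"])
        if "models" in doc:
            cfg.models = tuple(doc["models"])
        if "alpha" in doc:
            cfg.alpha = float(doc["alpha"])
        if "audit_margin" in doc:
            cfg.audit_margin = float(doc["audit_margin"])
        if "cv" in doc:
            cfg.cv_k = int(doc["cv"].get("k", cfg.cv_k))
            cfg.cv_repeats = int(doc["cv"].get("repeats", cfg.cv_repeats))
        if "cohort" in doc:
            cfg.cohort = dataclasses.replace(cfg.cohort, **doc["cohort"])
        if "train" in doc:
            cfg.train_cfg = dataclasses.replace(cfg.train_cfg, **doc["train"])
        if "ga" in doc:
            ga = dict(doc["ga"])
            if "gene_bounds" in ga:
                ga["gene_bounds"] = tuple(ga["gene_bounds"])
            cfg.ga_cfg = dataclasses.replace(cfg.ga_cfg, **ga)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["response_coeffs"] = [
            dataclasses.asdict(r) for r in self.cohort.response_coeffs
        ]
        return d


def _derive_stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {stage: int(rng.integers(0, 2**31 - 1)) for stage in _STAGES}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages into ``outdir``; returns the run directory.

    A stage failure aborts the run with the failing stage named; artifacts of
    completed stages are retained.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = _derive_stage_seeds(cfg.seed)
    artifacts: dict[str, Path] = {}
    retained = None
    models = {}
    scalers = {}

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("simulate"):
            spec = dataclasses.replace(cfg.cohort, seed=stage_seeds["simulate"])
            cohort = generate_cohort(spec)
            path = outdir / "cohort.csv"
            write_cohort(cohort, path, spec=spec)
            artifacts["cohort"] = path
            artifacts["cohort_spec"] = path.with_suffix(".csv.json")
            logger.info("simulate: wrote %d cases", len(cohort))
        else:
            raise ValueError("pipeline currently requires the simulate stage as data source")

        if _stage("filter"):
            retained, report = mahalanobis_filter(cohort, cfg.alpha)
            path = outdir / "retained.csv"
            write_cohort(retained, path, sidecar=False)
            rpath = outdir / "outliers.json"
            rpath.write_text(json.dumps(report.to_dict(), indent=2))
            artifacts["retained"] = path
            artifacts["outlier_report"] = rpath
            logger.info("filter: retained %d / %d", report.retained_count, len(cohort))
        else:
            retained = cohort

        if _stage("regress"):
            table = association_table(retained)
            frame = association_frame(table)
            path = outdir / "association.csv"
            path.write_text(frame.to_csv(index=False))
            jpath = outdir / "association.json"
            jpath.write_text(
                json.dumps({k: v.to_dict() for k, v in table.items()}, indent=2)
            )
            artifacts["association"] = path
            artifacts["association_json"] = jpath

        if _stage("train"):
            scaler = fit_scaler(retained)
            X, Y = apply_scaler(retained, scaler)
            for kind in cfg.models:
                tcfg = dataclasses.replace(cfg.train_cfg, shuffle_seed=stage_seeds["train"])
                if kind == "bp":
                    params, _ = train(NetworkParams.random(stage_seeds["train"]), X, Y, tcfg)
                else:
                    gcfg = dataclasses.replace(cfg.ga_cfg, seed=stage_seeds["train"])
                    params, _ = ga_bp_train(X, Y, gcfg, tcfg)
                path = outdir / f"model_{kind.replace('-', '_')}.json"
                save_model(params, scaler, path, seed=stage_seeds["train"])
                artifacts[f"model_{kind}"] = path
                models[kind] = params
                scalers[kind] = scaler

        if _stage("evaluate"):
            report_doc = {}
            for kind in cfg.models:
                rep = run_cv(
                    retained,
                    kind,
                    seed=stage_seeds["evaluate"],
                    train_cfg=cfg.train_cfg,
                    ga_cfg=cfg.ga_cfg,
                    k=cfg.cv_k,
                    repeats=cfg.cv_repeats,
                )
                report_doc[kind] = rep.to_dict()
            path = outdir / "report.json"
            path.write_text(json.dumps(report_doc, indent=2, sort_keys=True))
            artifacts["report"] = path

        if _stage("audit"):
            if not models:
                raise ValueError("audit stage requires the train stage")
            kind = cfg.models[-1]
            feats = np.array([r.features() for r in retained])
            preds = predict(models[kind], scalers[kind], feats)
            predictions = {
                r.case_id: dict(zip(OUTPUT_NAMES, row)) for r, row in zip(retained, preds)
            }
            plans = [PlanDoseSummary(case_id=r.case_id, v5=r.v5, v10=r.v10) for r in retained]
            flags = audit(plans, predictions, margin=cfg.audit_margin)
            path = outdir / "audit.csv"
            path.write_text(audit_frame(flags).to_csv(index=False))
            artifacts["audit"] = path
    except Exception as exc:
        failed = _failing_stage(artifacts)
        raise RuntimeError(f"pipeline failed during stage {failed!r}: {exc}") from exc

    manifest = {
        "package_version": dvhpredict.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _failing_stage(artifacts: dict) -> str:
    done = set(artifacts)
    if "report" in done:
        return "audit"
    if any(k.startswith("model_") for k in done):
        return "evaluate"
    if "association" in done:
        return "train"
    if "retained" in done:
        return "regress"
    if "cohort" in done:
        return "filter"
    return "simulate"
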