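"""End-to-end pipeline: simulate -> extract -> cross-validate -> report.

A single validated configuration drives every stage; each written artifact
carries the configuration hash so artifacts from different runs cannot be
mixed silently, and the whole pipeline is deterministic given the config
(including its seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cohort_io
from .features import (
    FeatureConfig,
    FeatureTable,
    extract_features,
    integrate_control,
)
from .metrics import MetricsReport, confusion_counts, compute_metrics, report
from .model import ClassifierSpec, MassPrediction, grouped_loo_cv
from .simulate import CohortConfig, Protocol, simulate_cohort

__all__ = [
    "PipelineConfig",
    "CohortSettings",
    "FeatureSettings",
    "ModelSettings",
    "EvaluationReport",
    "run_pipeline",
    "config_hash",
    "load_config",
]

logger = logging.getLogger(__name__)


class ProtocolSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_duration: float = 60.0
    heat_duration: float = 10.0
    target_heat_rise: float = 7.0
    sampling_rate: float = 10.0
    grid_side: int = 5
    region_size: float = 1.5

    def build(self) -> Protocol:
        return Protocol(**self.model_dump())


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_dogs: int = 45
    masses_per_dog_probs: tuple[float, ...] = (24 / 45, 18 / 45, 3 / 45)
    malignancy_prevalence: float = 27 / 69
    delta_base_mean: float = 1.0
    delta_base_sd: float = 0.3
    lambda_ratio: float = 1.3
    lambda_ratio_log_sd: float = 0.1
    pixel_noise_sd: float = 0.05
    dog_lambda_log_sd: float = 0.10
    dog_baseline_sd: float = 0.3
    mass_lambda_log_sd: float = 0.05
    mass_baseline_sd: float = 0.05
    control_baseline_c: float = 34.0
    kappa_geom: float = 0.02
    exact_counts: bool = False
    exact_prevalence: bool = False
    protocol: ProtocolSettings = Field(default_factory=ProtocolSettings)

    def build(self, seed: int) -> CohortConfig:
        d = self.model_dump()
        d["protocol"] = self.protocol.build()
        return CohortConfig(rng_seed=seed, **d)


class FeatureSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    harmonics: int = 8
    detrend: bool = True
    integration_mode: str = "subtract"

    def build(self) -> FeatureConfig:
        return FeatureConfig(**self.model_dump())


class ModelSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kernel: str = "linear"
    c: float = 1.0
    class_weight: Optional[str] = None
    n_features: int = 4
    per_fold_selection: bool = True
    tau: float = 0.5

    def build(self) -> ClassifierSpec:
        d = self.model_dump()
        d.pop("tau")
        return ClassifierSpec(**d)


class PipelineConfig(BaseModel):
    """Schema-validated configuration of the whole pipeline.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.
    """

    model_config = ConfigDict(extra="forbid")
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    features: FeatureSettings = Field(default_factory=FeatureSettings)
    model: ModelSettings = Field(default_factory=ModelSettings)
    rng_seed: int = 0
    log_level: str = "INFO"


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig.model_validate(data or {})


@dataclass(frozen=True)
class EvaluationReport:
    """End-to-end result: per-mass predictions plus the five metrics."""

    predictions: tuple  # MassPrediction, one per mass
    metrics: MetricsReport
    config_hash: str


def _check_hash(artifact_hash: str | None, expected: str, what: str) -> None:
    if artifact_hash is not None and artifact_hash != expected:
        raise ValueError(
            f"{what} was produced under a different configuration "
            f"({artifact_hash[:12]} != {expected[:12]}); refusing to mix artifacts"
        )


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> EvaluationReport:
    """Run simulate -> extract -> grouped LOO-CV -> report.

    When ``out_dir`` is given, every stage writes its artifact there
    (cohort CSV + manifest, feature table, predictions, metrics) plus a
    pipeline manifest with the config hash and stage checksums.  The
    result is deterministic given the config.
    """
    chash = config_hash(config)
    out = Path(out_dir) if out_dir is not None else None
    stage_checksums: dict[str, str] = {}

    def _finish(stage: str, started: float) -> None:
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - started)

    try:
        t0 = time.perf_counter()
        cohort_cfg = config.cohort.build(config.rng_seed)
        records = simulate_cohort(cohort_cfg)
        if out is not None:
            cohort_dir = out / "cohort"
            cohort_io.write_cohort(records, cohort_dir, config=cohort_cfg, config_hash=chash)
            stage_checksums["cohort"] = _file_sha(cohort_dir / "signals.csv")
        _finish("simulate", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        feat_cfg = config.features.build()
        protocol = cohort_cfg.protocol
        site, control = extract_features(records, protocol, feat_cfg)
        integrated = integrate_control(site, control, feat_cfg.integration_mode)
        if out is not None:
            write_feature_table(integrated, out / "features.csv", feat_cfg, chash)
            stage_checksums["features"] = _file_sha(out / "features.csv")
        _finish("extract", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'extract' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        spec = config.model.build()
        predictions = grouped_loo_cv(integrated, spec, tau=config.model.tau)
        _finish("classify", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        if out is not None:
            metrics = report(predictions, out, config_hash=chash)
            stage_checksums["metrics"] = _file_sha(out / "metrics.json")
            manifest = {
                "config": config.model_dump(mode="json"),
                "config_hash": chash,
                "rng_seed": config.rng_seed,
                "stage_checksums": stage_checksums,
            }
            with open(out / "pipeline_manifest.json", "w", encoding="utf-8", newline="\n") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
        else:
            metrics = compute_metrics(confusion_counts(predictions))
        _finish("report", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'report' failed: {exc}") from exc

    return EvaluationReport(
        predictions=tuple(predictions), metrics=metrics, config_hash=chash
    )


def _file_sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    feat_cfg: FeatureConfig | None = None,
    chash: str | None = None,
) -> None:
    """CSV with metadata columns first, plus a JSON sidecar of the config."""
    path = Path(path)
    table.data.to_csv(path, index=False, lineterminator="\n")
    sidecar = {
        "state": table.state,
        "config": None if feat_cfg is None else {
            "harmonics": feat_cfg.harmonics,
            "detrend": feat_cfg.detrend,
            "integration_mode": feat_cfg.integration_mode,
        },
        "config_hash": chash,
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_feature_table(path: str | Path, expected_hash: str | None = None) -> FeatureTable:
    """Read a feature CSV + sidecar; refuses a config-hash mismatch."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    state = "control-integrated"
    if sidecar_path.exists():
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
        state = sidecar.get("state", state)
        if expected_hash is not None:
            _check_hash(sidecar.get("config_hash"), expected_hash, str(path))
    return FeatureTable(pd.read_csv(path), state)
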