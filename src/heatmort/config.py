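"""Pipeline configuration: one YAML document, validated, hashable.

Unknown keys are rejected so typos fail loudly; every artifact written by
the pipeline embeds the config's content hash, the seed, and the package
version in its metadata sidecar so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .synthetic import RegionConfig

__all__ = ["TrainConfig", "InterpolatorFitConfig", "AttributionSettings",
           "ProjectionSettings", "PipelineConfig", "load_config",
           "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration document fails validation."""


class TrainConfig(BaseModel):
    """Exposure-model training settings (80:20 temporal split analogue)."""

    model_config = ConfigDict(extra="forbid")

    train_years: tuple[int, int] = (2011, 2018)
    validation_years: tuple[int, int] = (2019, 2020)
    ensemble_size: int = Field(default=20, ge=1)
    variant: str = "exponential"
    lag_days: int = Field(default=7, ge=1)
    hidden_dim: int = Field(default=8, ge=1)
    dow_correction: bool = True
    l2_reg: float = 0.02
    n_rounds: int = 2
    base_iters: int = 100
    net_iters: int = 250
    seeds: list[int] | None = None
    metric_exclusion_years: list[int] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        tr = set(range(self.train_years[0], self.train_years[1] + 1))
        va = set(range(self.validation_years[0], self.validation_years[1] + 1))
        if tr & va:
            raise ValueError("train_years and validation_years must be disjoint")
        if self.variant not in ("exponential", "linear"):
            raise ValueError("variant must be 'exponential' or 'linear'")
        if self.seeds is not None and len(self.seeds) < self.ensemble_size:
            raise ValueError("fewer seeds than ensemble_size")
        return self


class InterpolatorFitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha_init: float = 1.0
    train_fraction: float = Field(default=0.8, gt=0.0, le=1.0)
    max_iter: int = 300


class AttributionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cap_c: float = 20.0
    per_million: bool = True
    top_k: int = Field(default=10, ge=1)
    event_window: tuple[str, str] | None = None


class ProjectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_members: int = Field(default=50, ge=1)
    baseline_ref_date: str = "2020-12-28"
    dow_correction: bool = False


class PipelineConfig(BaseModel):
    """Top-level configuration of the simulate->fit->attribute->project pipeline."""

    model_config = ConfigDict(extra="forbid")

    region: RegionConfig = Field(default_factory=RegionConfig)
    interpolator: InterpolatorFitConfig = Field(default_factory=InterpolatorFitConfig)
    training: TrainConfig = Field(default_factory=TrainConfig)
    attribution: AttributionSettings = Field(default_factory=AttributionSettings)
    projection: ProjectionSettings = Field(default_factory=ProjectionSettings)
    seed: int = 0
    output_dir: str = "output"
    log_level: str = "INFO"


def config_hash(config: PipelineConfig) -> str:
    """Stable content hash of the validated configuration."""
    doc = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    An empty document yields all defaults.  Validation errors are re-raised
    as :class:`ConfigError` naming the offending key.
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("configuration document must be a mapping")
            doc = loaded
    if overrides:
        doc.update(overrides)
    try:
        return PipelineConfig.model_validate(doc)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ConfigError(f"invalid configuration ({locs})") from err
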