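"""Validated run configuration for the end-to-end pipeline.

The YAML config is validated against a pydantic schema before any
computation; every stochastic stage derives its seed from the single
``master_seed`` recorded in the provenance file, so a run can be reproduced
from its config alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pydantic
import yaml

from .analysis import PipelineSettings
from .errors import ConfigurationError
from .synthetic import SyntheticConfig


class SyntheticSection(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    n_subjects: int = pydantic.Field(default=31, ge=1)
    n_objects: int = pydantic.Field(default=5, ge=1)
    n_trials_per_object: int = pydantic.Field(default=7, ge=1)
    subject_effect_scale: float = pydantic.Field(default=1.0, ge=0)
    trial_noise_scale: float = pydantic.Field(default=0.25, ge=0)
    object_effect_scale: float = pydantic.Field(default=1.0, ge=0)
    mains_noise_amplitude: float = pydantic.Field(default=0.05, ge=0)
    sensor_noise_std: float = pydantic.Field(default=0.02, ge=0)
    marker_noise_std_mm: float = pydantic.Field(default=0.1, ge=0)
    kinematic_rate: float = pydantic.Field(default=120.0, gt=0)
    force_rate: float = pydantic.Field(default=960.0, gt=0)
    spring_constant: float = pydantic.Field(default=0.45, gt=0)


class FilterSection(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    lowpass_cutoff_hz: float = pydantic.Field(default=15.0, gt=0)
    bandstop_center_hz: float = pydantic.Field(default=50.0, gt=0)


class EmbeddingSection(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    dims: int = pydantic.Field(default=3, ge=2, le=3)
    perplexity: float = pydantic.Field(default=13.0, gt=0)
    tsne_max_iter: int = pydantic.Field(default=1000, ge=250)


class SensitivitySection(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    enabled: bool = False
    min_size: int = pydantic.Field(default=2, ge=1)
    max_size: int = pydantic.Field(default=14, ge=1)
    n_repeats: int = pydantic.Field(default=3, ge=1)


class PipelineConfig(pydantic.BaseModel):
    """Full pipeline configuration (see the package docs for field meaning)."""

    model_config = pydantic.ConfigDict(extra="forbid")

    synthetic: SyntheticSection = SyntheticSection()
    filters: FilterSection = FilterSection()
    embedding: EmbeddingSection = EmbeddingSection()
    normalization_mode: str = "full"
    angles_only: bool = False
    k_neighbors: int = pydantic.Field(default=10, ge=1)
    n_folds: int = pydantic.Field(default=5, ge=2)
    sensitivity: SensitivitySection = SensitivitySection()
    master_seed: int = 0
    log_level: str = "INFO"

    @pydantic.field_validator("normalization_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        from .features import MODES
        if v not in MODES:
            raise ValueError(f"normalization_mode must be one of {MODES}")
        return v

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.master_seed, **self.synthetic.model_dump())

    def pipeline_settings(self) -> PipelineSettings:
        return PipelineSettings(
            dims=self.embedding.dims,
            perplexity=self.embedding.perplexity,
            k_neighbors=self.k_neighbors,
            n_folds=self.n_folds,
            tsne_max_iter=self.embedding.tsne_max_iter,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: Path | str) -> PipelineConfig:
    """Load and validate a YAML pipeline config; raises ConfigurationError
    with a descriptive message before any computation starts."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except pydantic.ValidationError as e:
        raise ConfigurationError(f"invalid pipeline config {path}:\n{e}") from e
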