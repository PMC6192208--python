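"""Run configuration: YAML/JSON-backed settings for the CLI pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

__all__ = ["RunConfig", "SamplerSettings", "DataPaths", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run configuration (message includes the field path)."""


class SamplerSettings(BaseModel):
    n_chains: int = Field(32, ge=2)
    swap_prob: float = Field(0.99, gt=0, lt=1)
    mh_steps: int = Field(5, ge=1)
    burn_in: int = Field(50_000, ge=0)
    n_samples: int = Field(200_000, ge=1)
    subsample: int = Field(100, ge=1)
    adapt_every: int = Field(50, ge=1)
    reblock_every: int = Field(10_000, ge=100)


class DataPaths(BaseModel):
    time_course: Optional[str] = None
    steady_state: Optional[str] = None
    validation_rates: Optional[str] = None
    truth: Optional[str] = None
    draws_dir: Optional[str] = None


class RunConfig(BaseModel):
    """Declarative description of one synthetic-study pipeline run."""

    variant: int | Literal["reduced"] = "reduced"
    period_s: float = Field(4800.0, gt=0)
    seed: int = 1
    truth_mode: Literal["preset", "prior-draw"] = "preset"
    prior_overrides: dict[str, tuple[float, float]] = Field(default_factory=dict)
    fixed: dict[str, float] = Field(default_factory=dict)
    fix_at_truth: list[str] = Field(default_factory=list)
    log_base: Literal["e", "2"] = "e"
    n_dense: int = Field(481, ge=51)
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    data: DataPaths = Field(default_factory=DataPaths)
    outdir: str = "cyclebayes_out"

    @field_validator("variant")
    @classmethod
    def _check_variant(cls, v):
        if isinstance(v, int) and v not in (1, 2, 3, 4):
            raise ValueError("variant must be 1-4 or 'reduced'")
        return v

    def require_paths(self, *fields: str) -> dict[str, Path]:
        """Resolve dataset paths, insisting that they exist."""
        out = {}
        for f in fields:
            p = getattr(self.data, f)
            if p is None:
                raise ConfigError(f"data.{f}: path required for this command")
            path = Path(p)
            if not path.exists():
                raise ConfigError(f"data.{f}: file not found: {path}")
            out[f] = path
        return out


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: invalid YAML: {e}") from e
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in e.errors()
        )
        raise ConfigError(f"{path}: {locs}") from e
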