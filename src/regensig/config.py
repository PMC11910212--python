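"""Pipeline configuration: schema, validation and hashing.

Configs are YAML or JSON.  Validation is collect-all, not fail-fast: every
schema violation is reported at once with its field path.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigError


class ExperimentSpec(BaseModel):
    """Declaration of one input experiment (paths plus design metadata)."""

    experiment_id: str
    path: str
    species: Literal["mouse", "human"]
    platform: str = ""
    design_path: Optional[str] = None
    fc_column: Optional[str] = None  # set when the table holds precomputed log2fc
    high_group: str = "high_regeneration"  # group label meaning high regeneration
    low_group: str = "low_regeneration"

    @model_validator(mode="after")
    def _design_or_fc(self):
        if self.fc_column is None and self.design_path is None:
            raise ValueError(
                "either design_path (intensity table) or fc_column (precomputed "
                "fold changes) is required"
            )
        return self


class PipelineConfig(BaseModel):
    """Full configuration of a meta-analysis run."""

    experiments: list[ExperimentSpec] = Field(min_length=1)
    alias_path: Optional[str] = None
    ortholog_path: Optional[str] = None
    terms_path: Optional[str] = None  # GMT
    n_top: int = Field(default=200, ge=0)
    collapse: Literal["median", "mean", "max_abs"] = "median"
    mode: Literal["per-dataset", "aggregate"] = "per-dataset"
    floor: Optional[float] = Field(default=None, gt=0)
    permutations: int = Field(default=10_000, ge=0)
    seed: int = 0
    adjustment: Literal["bh", "bonferroni", "both"] = "both"
    out_dir: Optional[str] = None

    @field_validator("experiments")
    @classmethod
    def _unique_ids(cls, v: list[ExperimentSpec]) -> list[ExperimentSpec]:
        seen: set[str] = set()
        for e in v:
            if e.experiment_id in seen:
                raise ValueError(f"duplicate experiment_id {e.experiment_id!r}")
            seen.add(e.experiment_id)
        return v

    def config_hash(self) -> str:
        # out_dir does not alter what is computed, only where it lands
        payload = json.dumps(
            self.model_dump(exclude={"out_dir"}), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; report all errors at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"{path}: {len(lines)} config error(s):\n  " + "\n  ".join(lines)
        ) from exc
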