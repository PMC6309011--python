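"""Experiment configuration, validation and tabular output.

Configurations are validated strictly (unknown keys rejected) and
round-trip losslessly through YAML or JSON.  CSV output uses a fixed
column order and 12-significant-digit floats so that identical
configurations produce byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .resource_model import ModelParams, PRESETS

__all__ = [
    "ExperimentConfig",
    "ModelParamsConfig",
    "OracleConfig",
    "SolverConfig",
    "load_config",
    "write_tables",
    "SWEEP_COLUMNS",
]

#: Fixed column order of the sweep table.
SWEEP_COLUMNS = ["theta", "group_type", "N", "xbar_N", "K_rel", "feasible", "is_opt"]
_FLOAT_FORMAT = "%.12g"


class ModelParamsConfig(BaseModel):
    """Serializable mirror of :class:`~groupforage.resource_model.ModelParams`."""

    model_config = ConfigDict(extra="forbid")

    f_max: float = Field(3.0, gt=0)
    c0: float = Field(4.0, gt=0)
    m_b: float = Field(0.1, ge=0, le=1)
    o_m: float = Field(1.0, ge=0)

    def to_params(self, theta: float = 1.0) -> ModelParams:
        return ModelParams(f_max=self.f_max, c0=self.c0, m_b=self.m_b, o_m=self.o_m, theta=theta)

    @classmethod
    def from_preset(cls, name: str) -> "ModelParamsConfig":
        p = PRESETS[name]
        return cls(f_max=p.f_max, c0=p.c0, m_b=p.m_b, o_m=p.o_m)


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    root_rtol: float = Field(1e-12, gt=0)
    quad_epsabs: float = Field(1e-9, gt=0)


class OracleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_groups: int = Field(100_000, ge=1)
    seed: int = Field(0, ge=0)


class ExperimentConfig(BaseModel):
    """Full description of one reproducible experiment run."""

    model_config = ConfigDict(extra="forbid")

    params: ModelParamsConfig = ModelParamsConfig()
    theta_grid: list[float] = Field(default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
    group_types: list[Literal["egalitarian", "eusocial"]] = Field(
        default_factory=lambda: ["egalitarian", "eusocial"]
    )
    equilibrium_theta: float = Field(5.0, gt=0, description="theta of the per-N table")
    n_max_override: int | None = Field(None, ge=1)
    solver: SolverConfig = SolverConfig()
    oracle: OracleConfig = OracleConfig()
    output_dir: str = "output"

    @field_validator("theta_grid")
    @classmethod
    def _grid_valid(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("theta_grid must be nonempty")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("theta_grid must be strictly increasing")
        if any(t <= 0 for t in v):
            raise ValueError("theta values must be positive")
        return v

    @field_validator("group_types")
    @classmethod
    def _types_valid(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("group_types must be nonempty")
        return v


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r} (use .yaml/.yml/.json)")
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return ExperimentConfig.model_validate(data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write a configuration back to YAML or JSON (lossless round-trip)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")


def write_tables(frames: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named DataFrames as deterministic CSVs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in frames.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        written.append(path)
    return written
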