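"""Run configuration: a single validated YAML file drives every run.

Unknown keys are rejected, every default is applied explicitly, and the
effective configuration is echoed alongside the outputs so a run directory
is always sufficient to reproduce the run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .params import ModelParams
from .scenarios import ScenarioSpec
from .solver import SolverConfig

__all__ = ["GridConfig", "OutputConfig", "RunConfig", "load_config", "dump_config"]

CONFIG_SCHEMA_VERSION = 1


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    b_omega: float = Field(1.0, gt=0)
    n_nodes: int = Field(500, ge=8)


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "runs"
    formats: list[str] = Field(default_factory=lambda: ["csv"])
    snapshot_times: list[float] | None = Field(
        None, description="overrides solver.output_times when set"
    )

    @model_validator(mode="after")
    def _check(self) -> "OutputConfig":
        for fmt in self.formats:
            if fmt not in ("csv", "h5"):
                raise ValueError(f"unknown output format {fmt!r} (use 'csv' or 'h5')")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = CONFIG_SCHEMA_VERSION
    grid: GridConfig = Field(default_factory=GridConfig)
    params: ModelParams = Field(default_factory=ModelParams)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    scenario: ScenarioSpec = Field(default_factory=ScenarioSpec)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if self.scenario.sweep_param is not None:
            if self.scenario.sweep_param not in ModelParams.model_fields:
                raise ValueError(
                    f"sweep_param {self.scenario.sweep_param!r} is not a model parameter"
                )
        if self.scenario.bulk_extent >= self.grid.b_omega:
            raise ValueError("scenario.bulk_extent must be below grid.b_omega")
        if self.params.h_p >= self.grid.b_omega:
            raise ValueError("params.h_p must be below grid.b_omega")
        return self

    @property
    def effective_output_times(self) -> list[float]:
        if self.output.snapshot_times is not None:
            return self.output.snapshot_times
        return self.solver.output_times


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = all defaults)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the fully resolved configuration back out as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
    return path
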