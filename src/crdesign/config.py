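"""Run configuration: validated, YAML-serialisable settings for the CLI."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .design import CriterionSpec
from .information import ContinuousDesign
from .model import CRParams, DoseInterval
from .pso import PSOConfig


class PSOSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    swarm_size: int = 25
    max_iterations: int = 700
    cognitive: float = 2.5
    social: float = 0.5
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    relaxation: float = 1.5
    n_restarts: int = 5
    vmax_fraction: float = 0.2

    def to_pso_config(self, seed: int) -> PSOConfig:
        return PSOConfig(seed=seed, **self.model_dump())


class DesignSpec(BaseModel):
    """One simulation scenario: an explicit design with a label."""

    model_config = ConfigDict(extra="forbid")

    label: str
    doses: list[float]
    weights: list[float]

    def to_design(self) -> ContinuousDesign:
        return ContinuousDesign(self.doses, self.weights)


class RunConfig(BaseModel):
    """Everything a CLI run needs; round-trips losslessly through YAML."""

    model_config = ConfigDict(extra="forbid")

    alpha_tox: float
    beta_tox: float
    alpha_eff: float
    beta_eff: float
    gamma: float = 0.2
    dose_lower: float = 0.0
    dose_upper: float = 10.0
    criterion: str = "D"
    restricted: bool = False
    k: int = 4
    n: int = 40
    n_reps: int = 1000
    seed: int = 0
    grid_size: int = 1001
    get_tol: float = 1e-3
    pso: PSOSettings = Field(default_factory=PSOSettings)
    designs: Optional[list[DesignSpec]] = None
    output_dir: str = "."

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        # constructing the domain objects runs every component invariant
        self.params()
        self.interval()
        self.criterion_spec()
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n < 1 or self.n_reps < 2:
            raise ValueError("need n >= 1 and n_reps >= 2")
        if self.grid_size < 11:
            raise ValueError("grid too coarse: grid_size must be >= 11")
        return self

    def params(self) -> CRParams:
        return CRParams(self.alpha_tox, self.beta_tox, self.alpha_eff, self.beta_eff)

    def interval(self) -> DoseInterval:
        return DoseInterval(self.dose_lower, self.dose_upper)

    def criterion_spec(self) -> CriterionSpec:
        return CriterionSpec(self.criterion, self.restricted, self.gamma)

    def pso_config(self) -> PSOConfig:
        return self.pso.to_pso_config(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
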