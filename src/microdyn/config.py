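"""Validated run configuration (YAML) for the pipeline and CLI.

Every stochastic stage must end up with an explicit seed after config
resolution: a config without a top-level ``seed`` (and no CLI override) is
rejected rather than silently falling back to a random one.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_vars: int = Field(3, ge=1)
    n_steps: int = Field(100, ge=1)
    noise_sd: float = Field(1.5, ge=0)
    stability: Literal["stable", "unstable", "any"] = "stable"
    n_metabolites: Optional[int] = Field(None, ge=1)


class ImputeConfig(_Strict):
    kernel: Literal["rbf", "matern32"] = "rbf"
    level: float = Field(0.95, gt=0, lt=1)
    log1p: bool = False
    n_restarts: int = Field(5, ge=0)


class PriorConfig(_Strict):
    coeff: Literal["normal", "horseshoe"] = "normal"
    coeff_scale: float = Field(1.0, gt=0)
    intercept_scale: float = Field(5.0, gt=0)
    noise_scale: float = Field(1.0, gt=0)
    lkj_eta: Optional[float] = Field(None, gt=0)

    def to_prior_spec(self):
        from .inference import PriorSpec

        return PriorSpec(
            coeff_prior=(self.coeff, self.coeff_scale),
            intercept_prior=("normal", self.intercept_scale),
            noise_prior=("halfnormal", self.noise_scale),
            covariance_prior=None if self.lkj_eta is None else ("lkj", self.lkj_eta),
        )


class MCMCConfig(_Strict):
    chains: int = Field(4, ge=2)
    tune: int = Field(3000, ge=1)
    draws: int = Field(2000, ge=1)
    thin: int = Field(2, ge=1)

    def to_settings(self):
        from .inference import MCMCSettings

        return MCMCSettings(
            chains=self.chains, tune=self.tune, draws=self.draws, thin=self.thin
        )


class InferConfig(_Strict):
    method: Literal["bayes", "linear"] = "bayes"
    priors: Optional[PriorConfig] = None
    mcmc: MCMCConfig = MCMCConfig()
    level: float = Field(0.95, gt=0, lt=1)


class StabilityConfig(_Strict):
    matrix: str = "A"
    threshold: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    """Top-level pipeline configuration: impute -> normalize -> infer ->
    stability, with one master seed from which stage seeds derive."""

    model: Literal["var", "mvar", "glv", "cr"] = "var"
    seed: Optional[int] = None
    normalize: bool = False
    simulate: SimulateConfig = SimulateConfig()
    impute: ImputeConfig = ImputeConfig()
    infer: InferConfig = InferConfig()
    stability: StabilityConfig = StabilityConfig()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if v is not None and not (0 <= v < 2**31):
            raise ValueError("seed must be in [0, 2**31)")
        return v

    def resolved_seed(self, override: int | None = None) -> int:
        seed = override if override is not None else self.seed
        if seed is None:
            raise ValueError(
                "no seed configured: set `seed:` in the config or pass --seed"
            )
        return int(seed)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig(**raw)
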