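"""Run configuration: a validated YAML schema tying the workflow together.

A run configuration names the model (built-in constructor or EQN file), the
data file, the prior block, MCMC settings, and the constraint/analysis block.
Validation happens before any compute; every seed used is recorded in the
outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .constraints import ConstraintSpec
from .data import StudyDesign, bell_design
from .eqn import read_eqn_file
from .inference import McmcSettings
from .model import MPTModel, build_2htsm, build_2htsm_bell
from .priors import (
    FixedSpec,
    GammaSpec,
    LKJSpec,
    NormalSpec,
    PriorSpec,
    TreeBUGSDeviation,
    informative_preset,
    matzke_klauer_preset,
)

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GroupMeanConfig(_Strict):
    dist: Literal["normal"] = "normal"
    loc: float = 0.0
    scale: float = 1.0
    scale_is: Literal["sd", "var"] = "sd"


class DeviationConfig(_Strict):
    dist: Literal["gamma", "treebugs_default", "fixed"] = "gamma"
    shape: float = 2.0
    rate: float = 3.0
    value: float = 0.0
    df: Optional[int] = None
    xi_upper: float = 10.0


class CorrelationConfig(_Strict):
    dist: Literal["lkj"] = "lkj"
    eta: float = 1.0


class PriorConfig(_Strict):
    preset: Optional[Literal["informative", "matzke_klauer"]] = None
    group_mean: dict[str, GroupMeanConfig] = Field(default_factory=dict)
    deviation: Optional[DeviationConfig] = None
    correlation: Optional[CorrelationConfig] = None

    def build(self, model: MPTModel) -> PriorSpec:
        if self.preset == "informative":
            base = informative_preset(model)
        elif self.preset == "matzke_klauer":
            base = matzke_klauer_preset(model)
        elif self.group_mean:
            base = PriorSpec(
                group_mean={
                    p: NormalSpec(c.loc, c.scale, c.scale_is)
                    for p, c in self.group_mean.items()
                },
                deviation=GammaSpec(),
                correlation=LKJSpec(),
            )
        else:
            raise ValueError("prior block needs a preset or explicit group_mean entries")
        group = dict(base.group_mean)
        for p, c in self.group_mean.items():
            group[p] = NormalSpec(c.loc, c.scale, c.scale_is)
        deviation = base.deviation
        correlation = base.correlation
        if self.deviation is not None:
            if self.deviation.dist == "gamma":
                deviation = GammaSpec(self.deviation.shape, self.deviation.rate)
            elif self.deviation.dist == "fixed":
                deviation = FixedSpec(self.deviation.value)
            else:
                deviation = TreeBUGSDeviation(self.deviation.df, self.deviation.xi_upper)
                correlation = None
        if self.correlation is not None:
            correlation = LKJSpec(self.correlation.eta)
        if isinstance(deviation, TreeBUGSDeviation):
            correlation = None
        elif correlation is None:
            correlation = LKJSpec()
        spec = PriorSpec(
            group_mean=group,
            deviation=deviation,
            correlation=correlation,
            preset=self.preset,
        )
        spec.validate(model)
        return spec


class McmcConfig(_Strict):
    profile: Literal["smoke", "paper", "custom"] = "smoke"
    draws: Optional[int] = None
    warmup: Optional[int] = None
    chains: Optional[int] = None
    thin: int = 1

    def build(self, seed: int) -> McmcSettings:
        if self.profile == "paper":
            base = McmcSettings.paper(seed=seed)
        else:
            base = McmcSettings.smoke(seed=seed)
        return McmcSettings(
            draws=self.draws or base.draws,
            warmup=self.warmup if self.warmup is not None else base.warmup,
            chains=self.chains or base.chains,
            seed=seed,
            thin=self.thin,
        )


class SimulateConfig(_Strict):
    design: Literal["bell", "custom"] = "bell"
    n_participants: int = 30
    items_per_tree: dict[str, int] = Field(default_factory=dict)
    truth: dict[str, float] = Field(default_factory=dict)
    sigma: float = 0.4

    def build_design(self, model: MPTModel) -> StudyDesign:
        if self.design == "bell":
            return bell_design(self.n_participants)
        if not self.items_per_tree:
            raise ValueError("custom design requires items_per_tree")
        return StudyDesign(
            items_per_tree=dict(self.items_per_tree), n_participants=self.n_participants
        )


class ConstraintsConfig(_Strict):
    scale: Literal["probability", "probit"] = "probability"
    level: Literal["group", "every_individual"] = "group"
    order: list[str] = Field(default_factory=list)
    null: list[str] = Field(default_factory=list)
    sd_method: Literal["logspline", "truncated_normal"] = "logspline"
    repetitions: int = 0
    prior_draws: int = 100_000

    @field_validator("null")
    @classmethod
    def _strip_eq(cls, v: list[str]) -> list[str]:
        out = []
        for item in v:
            if "==" in item:
                lhs, rhs = item.split("==")
                if float(rhs) != 0.0:
                    raise ValueError("only zero point nulls are supported in configs")
                item = lhs.strip()
            out.append(item)
        return out

    def build_order(self) -> ConstraintSpec | None:
        if not self.order:
            return None
        return ConstraintSpec.order(self.order, scale=self.scale, level=self.level)

    def build_null(self) -> ConstraintSpec | None:
        if not self.null:
            return None
        return ConstraintSpec.point_null(self.null, scale=self.scale)


class RunConfig(_Strict):
    model: str = "2htsm"
    conditions: list[str] = Field(default_factory=lambda: ["pleasant", "disgusting"])
    data: Optional[str] = None
    output: str = "ordtree_output"
    seed: int = 0
    prior: PriorConfig = Field(default_factory=lambda: PriorConfig(preset="informative"))
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    constraints: ConstraintsConfig = Field(default_factory=ConstraintsConfig)

    def build_model(self) -> MPTModel:
        if self.model == "2htsm":
            return build_2htsm()
        if self.model == "2htsm_bell":
            return build_2htsm_bell(tuple(self.conditions))
        path = Path(self.model)
        if not path.exists():
            raise FileNotFoundError(f"model {self.model!r}: not a built-in name or file")
        return read_eqn_file(path)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a YAML mapping")
    constraints = raw.get("constraints")
    if isinstance(constraints, dict) and None in constraints:
        # a bare "null:" key is parsed by YAML as the None scalar
        constraints["null"] = constraints.pop(None)
    return RunConfig.model_validate(raw)
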