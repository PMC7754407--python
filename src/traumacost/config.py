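"""Model configuration: schema, validation, loading, domain-object builders.

All model inputs — generator parameters, policy scenarios, the baseline
severity distribution, the annual transition matrix, age-based mortality,
per-state and per-condition costs, cohort sizes, sensitivity ranges and
the PSA specification — live in one YAML (or JSON) document. The packaged
default mirrors the published study where values are printed (baseline
state counts, diagnosis prevalence, per-trauma odds ratio, scenario
exposure fractions, cohort sizes) and carries clearly-labelled placeholder
values for the remaining inputs (transition probabilities, unit costs,
mortality), whose published sources sit in supplementary material not
reproduced here. Each input's provenance is recorded in the config itself.
"""

from __future__ import annotations

import copy
import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .cohort import GeneratorSpec
from .costs import CohortSpec, CostComponents, CostInputs
from .markov import MortalityTable, TransitionModel
from .scenarios import PolicyScenario, SeverityDistribution
from .severity import CONDITIONS, STATE_LABELS, PrevalenceTable, TraumaEffect

__all__ = ["ModelConfig", "ConfigError", "load_config", "default_config",
           "default_config_path", "set_config_path", "config_to_raw"]


class ConfigError(ValueError):
    """A configuration document failed schema validation."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="allow", populate_by_name=True)


class CostComponentsCfg(_Base):
    direct: float = Field(ge=0)
    indirect: float = Field(default=0.0, ge=0)


class CostsCfg(_Base):
    base_no_problems: CostComponentsCfg
    base_behavior_problems: CostComponentsCfg
    conditions: dict[str, CostComponentsCfg]
    currency_note: str = "2018 USD"
    conversion_factor: float = Field(default=1.0, gt=0)

    @field_validator("conditions")
    @classmethod
    def _check_conditions(cls, v):
        if set(v) != set(CONDITIONS):
            raise ValueError(f"conditions must be exactly {sorted(CONDITIONS)}, got {sorted(v)}")
        return v


class ScenarioCfg(_Base):
    name: str
    exposed_fraction: float = Field(ge=0.0, le=1.0)
    extra_traumas: int = Field(default=1, ge=0)


class GeneratorCfg(_Base):
    n: int = Field(default=458, ge=1)
    age_mean: float = 13.0
    age_sd: float = Field(default=4.0, gt=0)
    prop_male: float = Field(default=0.43, ge=0, le=1)
    trauma_mean: float = Field(default=3.6, ge=0)
    trauma_sd: float = Field(default=2.3, ge=0)
    baseline_cutpoints: list[float] | None = None
    beta_trauma: float = float(np.log(1.232))
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 20180401

    @field_validator("baseline_cutpoints")
    @classmethod
    def _increasing(cls, v):
        if v is not None and (len(v) != 3 or not all(a < b for a, b in zip(v, v[1:]))):
            raise ValueError("baseline_cutpoints must be 3 strictly increasing values")
        return v


class TraumaEffectCfg(_Base):
    or_point: float = Field(alias="or", gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)

    @field_validator("ci_high")
    @classmethod
    def _ordered(cls, v, info):
        low = info.data.get("ci_low")
        if low is not None and v < low:
            raise ValueError("ci_high must be >= ci_low")
        return v


class DSARangeCfg(_Base):
    path: str
    low: float
    high: float

    @field_validator("high")
    @classmethod
    def _ordered(cls, v, info):
        low = info.data.get("low")
        if low is not None and v < low:
            raise ValueError("high must be >= low")
        return v


class PSAParamCfg(_Base):
    path: str
    dist: Literal["lognormal", "gamma", "beta"]
    params: dict[str, float]


class PSACfg(_Base):
    iterations: int = Field(default=2000, ge=1)
    seed: int = 20180402
    parameters: list[PSAParamCfg] = Field(default_factory=list)


class CohortCfg(_Base):
    label: str
    size: int = Field(ge=1)


class ModelConfig(_Base):
    """Validated model configuration; see module docstring for the layout."""

    generator: GeneratorCfg = Field(default_factory=GeneratorCfg)
    trauma_effect: TraumaEffectCfg
    scenarios: list[ScenarioCfg]
    state_counts: list[int]
    prevalence_counts: dict[str, list[int]]
    transition_matrix: list[list[float]]
    progression_only: bool = True
    mortality: dict[int, float]
    start_age: int = Field(default=13, ge=0)
    horizons: list[int] = Field(default_factory=lambda: [5, 10])
    discount_rate: float = Field(default=0.0, ge=0.0)
    include_q1_conditions: bool = False
    costs: CostsCfg
    cohorts: list[CohortCfg]
    dsa_ranges: list[DSARangeCfg] = Field(default_factory=list)
    psa: PSACfg = Field(default_factory=PSACfg)
    provenance: dict[str, str] = Field(default_factory=dict)

    @field_validator("state_counts")
    @classmethod
    def _four_states(cls, v):
        if len(v) != 4 or any(c < 0 for c in v) or sum(v) == 0:
            raise ValueError("state_counts must be 4 non-negative counts with positive sum")
        return v

    @field_validator("horizons")
    @classmethod
    def _positive_horizons(cls, v):
        if not v or any(int(h) != h or h < 1 for h in v):
            raise ValueError("horizons must be positive integers")
        return v

    # ---- builders -------------------------------------------------------

    def to_generator_spec(self, prevalence: PrevalenceTable | None = None) -> GeneratorSpec:
        g = self.generator
        prev = prevalence if prevalence is not None else self.prevalence_table()
        kwargs = dict(
            n=g.n, age_mean=g.age_mean, age_sd=g.age_sd, prop_male=g.prop_male,
            trauma_mean=g.trauma_mean, trauma_sd=g.trauma_sd,
            beta_trauma=g.beta_trauma, beta_age=g.beta_age, beta_sex=g.beta_sex,
            seed=g.seed,
            prevalence_by_state={c: tuple(prev.by_state(c)) for c in CONDITIONS},
        )
        if g.baseline_cutpoints is not None:
            kwargs["baseline_cutpoints"] = tuple(g.baseline_cutpoints)
        return GeneratorSpec(**kwargs)

    def base_distribution(self) -> SeverityDistribution:
        return SeverityDistribution.from_counts(self.state_counts)

    def prevalence_table(self) -> PrevalenceTable:
        cols = list(STATE_LABELS) + ["full"]
        state_n = pd.Series(list(self.state_counts) + [sum(self.state_counts)], index=cols)
        counts = pd.DataFrame(index=list(CONDITIONS), columns=cols, dtype=float)
        for cond in CONDITIONS:
            per_state = self.prevalence_counts[cond]
            if len(per_state) != 4:
                raise ConfigError(f"prevalence_counts[{cond!r}] must have 4 entries")
            counts.loc[cond, list(STATE_LABELS)] = per_state
            counts.loc[cond, "full"] = sum(per_state)
        denom = state_n.astype(float).where(state_n > 0)
        return PrevalenceTable(counts=counts.astype(int),
                               proportions=counts.div(denom, axis=1), state_n=state_n)

    def to_trauma_effect(self) -> TraumaEffect:
        te = self.trauma_effect
        return TraumaEffect(or_point=te.or_point, or_low=te.ci_low, or_high=te.ci_high,
                            n=sum(self.state_counts))

    def to_scenarios(self) -> list[PolicyScenario]:
        return [PolicyScenario(s.name, s.exposed_fraction, s.extra_traumas)
                for s in self.scenarios]

    def to_transition_model(self) -> TransitionModel:
        return TransitionModel(tuple(map(tuple, self.transition_matrix)),
                               progression_only=self.progression_only)

    def to_mortality_table(self) -> MortalityTable:
        return MortalityTable(dict(self.mortality))

    def to_cost_inputs(self) -> CostInputs:
        c = self.costs
        return CostInputs(
            base_no_problems=CostComponents(c.base_no_problems.direct, c.base_no_problems.indirect),
            base_behavior_problems=CostComponents(
                c.base_behavior_problems.direct, c.base_behavior_problems.indirect),
            condition_costs={
                cond: CostComponents(cc.direct, cc.indirect)
                for cond, cc in c.conditions.items()
            },
            prevalence=self.prevalence_table(),
            include_q1_conditions=self.include_q1_conditions,
            currency_note=c.currency_note,
            conversion_factor=c.conversion_factor,
        )

    def to_cohort_specs(self) -> list[CohortSpec]:
        return [CohortSpec(c.label, c.size) for c in self.cohorts]


def _warn_unknown_keys(model: BaseModel, prefix: str = "") -> None:
    extra = getattr(model, "model_extra", None) or {}
    for key in extra:
        warnings.warn(f"unknown config key ignored: {prefix}{key}", stacklevel=3)
    for name in type(model).model_fields:
        value = getattr(model, name, None)
        if isinstance(value, BaseModel):
            _warn_unknown_keys(value, f"{prefix}{name}.")
        elif isinstance(value, list):
            for i, item in enumerate(value):
                if isinstance(item, BaseModel):
                    _warn_unknown_keys(item, f"{prefix}{name}[{i}].")


def _validate(raw: dict) -> ModelConfig:
    try:
        cfg = ModelConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {msgs}") from exc
    _warn_unknown_keys(cfg)
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _validate(raw)


def default_config_path() -> Path:
    return Path(resources.files("traumacost") / "data" / "default_config.yaml")


def default_config() -> ModelConfig:
    """The packaged default configuration (see module docstring on provenance)."""
    return load_config(default_config_path())


def config_to_raw(config: ModelConfig) -> dict:
    """Round-trippable plain-dict form of a config (for overrides)."""
    return copy.deepcopy(config.model_dump(by_alias=True))


def set_config_path(raw: dict, path: str, value: Any) -> dict:
    """Set a dotted-path key (e.g. ``costs.conditions.depression.direct``).

    List indices are written as plain integers in the path. Raises
    ConfigError if any intermediate segment is missing.
    """
    out = copy.deepcopy(raw)
    node = out
    parts = path.split(".")
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if isinstance(node, list):
            try:
                idx = int(part)
                node[idx]
            except (ValueError, IndexError):
                raise ConfigError(f"config path not found: {path} (at {part!r})") from None
            if last:
                node[idx] = value
            else:
                node = node[idx]
        elif isinstance(node, dict):
            if part not in node:
                raise ConfigError(f"config path not found: {path} (at {part!r})")
            if last:
                node[part] = value
            else:
                node = node[part]
        else:
            raise ConfigError(f"config path not found: {path} (at {part!r})")
    return out


def revalidate(raw: dict) -> ModelConfig:
    """Validate an in-memory raw config dict (after overrides)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _validate(raw)
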