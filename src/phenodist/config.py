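"""Declarative pipeline configuration with exhaustive validation.

All constants of the analysis are configuration, not code: the cleaning
thresholds (50 g, 30 birds, 6 weeks), the age phases (growing 14–19, adult
20–72), the 21 environmental layers, the boosting hyperparameters and the
N > 25 correlation gate all live here as defaults and can be overridden
from a YAML file.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError

__all__ = ["BoostingConfig", "EvaluationConfig", "FilterConfig", "PipelineConfig",
           "SimulateConfig"]


def _from_dict(cls, d: dict):
    if not isinstance(d, dict):
        raise ConfigurationError(f"{cls.__name__}: expected a mapping, got {type(d).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(d) - set(known)
    if unknown:
        raise ConfigurationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        sub = _NESTED.get((cls, name))
        kwargs[name] = _from_dict(sub, value) if sub else value
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    rows: int = 30
    cols: int = 30
    n_vars: int = 21
    n_regions: int = 5
    smoothness: float = 3.0
    nodata_fraction: float = 0.0
    n_households: int = 480
    breeds: list[str] = field(default_factory=lambda: ["Sasso", "Koekoek", "Horro"])
    active_vars: list[str] = field(
        default_factory=lambda: ["annual_mean_temp", "annual_precip", "elevation"]
    )
    amplitudes: list[float] = field(default_factory=lambda: [120.0, 90.0, 70.0])
    intercept: float = 40.0
    household_sd: float = 40.0
    residual_sd: float = 30.0
    slope_mean: float = 58.0
    slope_sd: float = 2.0
    ref_week: float = 16.5
    group_size_min: int = 3
    group_size_max: int = 25
    contaminate_under50: int = 10
    contaminate_over30_households: int = 5
    contaminate_under6wk: int = 10

    def validate(self):
        if not self.breeds:
            raise ConfigurationError("breeds must be nonempty")
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")


@dataclass
class FilterConfig:
    min_weight_g: float = 50.0
    max_birds: int = 30
    min_week: float = 6.0

    def validate(self):
        if self.min_weight_g <= 0 or self.max_birds <= 0 or self.min_week <= 0:
            raise ConfigurationError("filter thresholds must be positive")


@dataclass
class BoostingConfig:
    nu: float = 0.1
    knot_count: int = 20
    degree: int = 3
    penalty_order: int = 2
    target_df: float = 4.0
    m_max: int = 100
    cv_B: int = 25
    cv_scheme: str = "bootstrap"

    def validate(self):
        if not (0 < self.nu <= 1):
            raise ConfigurationError("nu must be in (0, 1]")
        if self.m_max < 1 or self.cv_B < 2:
            raise ConfigurationError("m_max >= 1 and cv_B >= 2 required")
        if self.cv_scheme not in ("bootstrap", "kfold"):
            raise ConfigurationError(f"unknown cv_scheme {self.cv_scheme!r}")


@dataclass
class EvaluationConfig:
    gate_n: int = 25
    method: str = "pearson"

    def validate(self):
        if self.gate_n < 0:
            raise ConfigurationError("gate_n must be >= 0")


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    region_statistic: str = "mean"

    def validate(self):
        self.simulate.validate()
        self.filters.validate()
        self.boosting.validate()
        self.evaluation.validate()
        if self.region_statistic not in ("mean", "median", "max"):
            raise ConfigurationError(f"unknown region_statistic {self.region_statistic!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


_NESTED = {
    (PipelineConfig, "simulate"): SimulateConfig,
    (PipelineConfig, "filters"): FilterConfig,
    (PipelineConfig, "boosting"): BoostingConfig,
    (PipelineConfig, "evaluation"): EvaluationConfig,
}
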