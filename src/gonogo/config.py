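"""Pipeline configuration: one YAML file drives a full reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, is_dataclass

import yaml

from .lba import LBAParams
from .synth import CohortConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RTFilterConfig:
    low: float = 0.2
    high: float = 1.0


@dataclass(frozen=True)
class LBAStageConfig:
    enabled: bool = True
    deadline: float = 1.0
    n_chains: int = 24
    n_steps: int = 900
    burn_in: int = 400


@dataclass(frozen=True)
class OutcomeStageConfig:
    horizon: int = 90
    study_length: int = 365


@dataclass(frozen=True)
class ModelStageConfig:
    # joint model with both behavioral predictors by default
    behavioral_predictors: tuple[str, ...] = ("pct_misses", "pct_false_alarms")
    lba_predictors: tuple[str, ...] = ("response_bias_go", "de_targets",
                                       "de_foils")
    covariates: tuple[str, ...] = ("session_label", "lifetime_asa_count",
                                   "ssi", "age", "gender", "tbi",
                                   "treatment_arm", "stroop_d")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    rt_filter: RTFilterConfig = field(default_factory=RTFilterConfig)
    lba: LBAStageConfig = field(default_factory=LBAStageConfig)
    outcome: OutcomeStageConfig = field(default_factory=OutcomeStageConfig)
    model: ModelStageConfig = field(default_factory=ModelStageConfig)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    cohort = dict(raw.get("cohort", {}))
    if "group_param_means" in cohort:
        cohort["group_param_means"] = {
            g: LBAParams(**p) for g, p in cohort["group_param_means"].items()
        }
    model = dict(raw.get("model", {}))
    for key in ("behavioral_predictors", "lba_predictors", "covariates"):
        if key in model:
            model[key] = tuple(model[key])
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        cohort=CohortConfig(**cohort),
        rt_filter=RTFilterConfig(**raw.get("rt_filter", {})),
        lba=LBAStageConfig(**raw.get("lba", {})),
        outcome=OutcomeStageConfig(**raw.get("outcome", {})),
        model=ModelStageConfig(**model),
    )
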