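"""Declarative pipeline configuration: defaults, range checks, normalization.

Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from metabosub.consensus import ConsensusConfig
from metabosub.errors import ValidationError
from metabosub.preprocess import PreprocessConfig


@dataclass
class SurvivalConfig:
    min_followup_months: float = 1.0
    cutpoint_minprop: float = 0.1

    def __post_init__(self) -> None:
        if self.min_followup_months < 0:
            raise ValidationError("min_followup_months must be >= 0")
        if not 0 < self.cutpoint_minprop < 0.5:
            raise ValidationError("cutpoint_minprop must lie in (0, 0.5)")


@dataclass
class MutationConfig:
    min_probes: int = 10
    mean_thresh: float = 0.2
    mc_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.min_probes < 0 or self.mean_thresh < 0 or self.mc_reps < 1:
            raise ValidationError("mutation thresholds out of range")


@dataclass
class PanCancerConfig:
    min_samples: int = 100
    homogeneity_min: float = 0.75

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")
        if not 0 <= self.homogeneity_min <= 1:
            raise ValidationError("homogeneity_min must lie in [0, 1]")


@dataclass
class PipelineConfig:
    seed: int = 0
    k: int = 4
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    pan_cancer: PanCancerConfig = field(default_factory=PanCancerConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "consensus": ConsensusConfig,
    "survival": SurvivalConfig,
    "mutation": MutationConfig,
    "pan_cancer": PanCancerConfig,
}


def _build_section(cls, data: dict, section: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    # tuple-typed fields arrive from YAML as lists
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Load and normalize a pipeline config, filling defaults.

    An empty/absent file yields all defaults. Unknown keys raise
    :class:`ValidationError` naming the offending key.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as handle:
                data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    top_valid = {"seed", "k"} | set(_SECTIONS)
    unknown = set(data) - top_valid
    if unknown:
        raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "k" in data:
        k = int(data["k"])
        if k < 2:
            raise ValidationError("k must be >= 2")
        kwargs["k"] = k
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_section(cls, data[section] or {}, section)
    config = PipelineConfig(**kwargs)
    if config.k not in config.consensus.k_values:
        config.consensus = ConsensusConfig(
            k_values=tuple(sorted({*config.consensus.k_values, config.k})),
            reps=config.consensus.reps, p_item=config.consensus.p_item,
            p_feature=config.consensus.p_feature,
            linkage_final=config.consensus.linkage_final,
            seed=config.consensus.seed)
    return config


def write_normalized(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
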