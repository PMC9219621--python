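"""Pipeline configuration: nested sections, YAML round-trip, strict keys.

Defaults match the published operating point of the two CAD branches:
segmentation alpha 0.1 / beta 0.5 with termination limits 2.0 and 0.5,
10-fold CV, PCA variance target 0.95, polynomial SVM, batch size 4, Adam
lr 1e-4 with per-epoch gamma 0.4 over 10 epochs, fusion weight W1 = 0.5 and
operating threshold 0.5.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classical import ClassicalConfig
from .dl import DLConfig
from .phantom import PhantomSpec
from .radiomics import RadiomicsConfig
from .segmentation import SegmentationParams


@dataclass(frozen=True)
class FusionConfig:
    w1: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError("w1 must lie in [0, 1]")


@dataclass(frozen=True)
class EvaluationConfig:
    threshold: float = 0.5
    n_bins: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    classical: ClassicalConfig = field(default_factory=ClassicalConfig)
    dl: DLConfig = field(default_factory=DLConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    n_malignant: int = 100
    n_benign: int = 100
    rng_seed: int = 0
    dl_enabled: bool = True
    out_dir: str = "mammocad_out"


_SECTIONS = {
    "phantom": PhantomSpec,
    "segmentation": SegmentationParams,
    "radiomics": RadiomicsConfig,
    "classical": ClassicalConfig,
    "dl": DLConfig,
    "fusion": FusionConfig,
    "evaluation": EvaluationConfig,
}


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys under '{path}': {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        coerced[f.name] = _tuplify(data[f.name])
    return cls(**coerced)


def _tuplify(v):
    if isinstance(v, (list, tuple)):
        return tuple(_tuplify(x) for x in v)
    return v


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {}, name)
    for name in ("n_malignant", "n_benign", "rng_seed", "dl_enabled",
                 "out_dir"):
        if name in data:
            kwargs[name] = data[name]
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    out: dict = {}
    for name, _cls in _SECTIONS.items():
        section = dataclasses.asdict(getattr(config, name))
        out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in section.items()}
    for name in ("n_malignant", "n_benign", "rng_seed", "dl_enabled",
                 "out_dir"):
        out[name] = getattr(config, name)
    return out


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
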