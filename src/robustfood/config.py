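"""Run configuration: nested dataclasses with YAML loading and validation.

Defaults are the full-scale protocol (channel widths 1024/256/64, fusion
weights 0.2/0.35/0.45, loss weights (0.6, 0.4), distillation alpha 0.5,
noise sigma 0.10, SGD lr 0.002 with cosine annealing, batch 32). Unknown
keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class DataSection:
    classes: int = 3
    per_class: int = 50
    image_size: int = 64
    split_ratios: tuple[float, float, float] = (0.6, 0.1, 0.3)
    resize_to: int = 550
    crop_to: int = 448


@dataclass
class ModelSection:
    backbone: str = "tiny"
    feature_channels: int = 1024       # D
    head_hidden: int = 256             # D'
    restore_channels: int = 64         # D''
    epsilon: float = 1e-5


@dataclass
class TrainingSection:
    lr0: float = 0.002
    epochs: int = 200
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0
    alpha: float = 0.6
    beta: float = 0.4
    seed: int = 0


@dataclass
class FusionSection:
    betas: tuple[float, ...] = (0.2, 0.35, 0.45)
    projection_channels: int | None = None   # defaults to feature_channels


@dataclass
class DistillSection:
    alpha: float = 0.5
    T_start: float = 0.5
    T_end: float = 2.0
    phase_1_epochs: int = 8
    phase_2_epochs: int = 2
    feature_align_weight: float = 0.0
    schedule: str = "rising"


@dataclass
class NoiseSection:
    sigma: float = 0.10
    clip: bool = True
    train_only: bool = True
    seed: int = 0


@dataclass
class EvalSection:
    topk: tuple[int, ...] = (1, 5)
    seeds: int = 5


@dataclass
class RunConfig:
    data: DataSection = field(default_factory=DataSection)
    model: ModelSection = field(default_factory=ModelSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    distill: DistillSection = field(default_factory=DistillSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    eval: EvalSection = field(default_factory=EvalSection)
    source_path: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("source_path")
        return d


_TUPLE_FIELDS = {"split_ratios", "betas", "topk"}


def _fill_section(obj, data: dict, section: str) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown configuration key '{section}.{key}'")
        if key in _TUPLE_FIELDS and value is not None:
            value = tuple(value)
        setattr(obj, key, value)


def _validate(cfg: RunConfig) -> None:
    checks = [
        (cfg.training.lr0 > 0, "training.lr0 must be > 0"),
        (cfg.training.epochs >= 1, "training.epochs must be >= 1"),
        (cfg.training.batch_size >= 1, "training.batch_size must be >= 1"),
        (cfg.training.alpha >= 0 and cfg.training.beta >= 0,
         "training.alpha/beta must be >= 0"),
        (all(b >= 0 for b in cfg.fusion.betas), "fusion.betas must be >= 0"),
        (0 <= cfg.distill.alpha <= 1, "distill.alpha must be in [0, 1]"),
        (cfg.distill.T_start > 0 and cfg.distill.T_end > 0,
         "distill temperatures must be > 0"),
        (cfg.noise.sigma >= 0, "noise.sigma must be >= 0"),
        (0 < cfg.model.epsilon < 1, "model.epsilon must be in (0, 1)"),
        (cfg.data.crop_to <= cfg.data.resize_to,
         "data.crop_to must be <= data.resize_to"),
        (cfg.data.classes >= 2, "data.classes must be >= 2"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ValueError(msg)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    cfg = RunConfig()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping of sections")
        sections = {f.name: getattr(cfg, f.name)
                    for f in dataclasses.fields(cfg) if f.name != "source_path"}
        for section, data in raw.items():
            if section not in sections:
                raise ValueError(f"unknown configuration section '{section}'")
            if data is None:
                continue
            if not isinstance(data, dict):
                raise ValueError(f"section '{section}' must be a mapping")
            _fill_section(sections[section], data, section)
        cfg.source_path = str(path)
    _validate(cfg)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
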