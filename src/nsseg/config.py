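"""Validated run configuration loaded from YAML.

Every stochastic or numeric knob of a run lives in one record; unknown keys
are rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .segmodel import ModelSpec
from .synthetic import LesionParams

__all__ = ["TrainConfig", "RunPaths", "SyntheticConfig", "RunConfig", "load_run_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file is malformed or contains unknown/invalid keys."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, schedule and noise hyperparameters of one training stage.

    Defaults follow the study recipe: SGD at lr0=0.002 with cosine
    annealing, momentum 0.54, weight decay 0.01, batch size 10, dice loss
    with smoothing λ=1, dropout 0.5 as model noise.
    """

    lr0: float = 0.002
    momentum: float = 0.54
    weight_decay: float = 0.01
    batch_size: int = 10
    epochs: int = 60
    dropout_p: float = 0.5
    smooth: float = 1.0
    augset_name: str = "simple"
    early_stop_patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or self.weight_decay < 0 or not 0 <= self.momentum < 1:
            raise ConfigError("invalid optimizer hyperparameters")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigError("batch_size must be >= 1 and epochs >= 0")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must be in [0, 1)")
        if self.smooth <= 0:
            raise ConfigError("dice smoothing must be positive")
        if self.early_stop_patience < 1:
            raise ConfigError("early_stop_patience must be >= 1")


@dataclass(frozen=True)
class RunPaths:
    out_dir: Path = Path("runs/out")
    labeled_manifest: Optional[Path] = None
    val_manifest: Optional[Path] = None
    test_manifest: Optional[Path] = None
    unlabeled_manifest: Optional[Path] = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters for generating the synthetic benchmark inside a run."""

    n: int = 100
    fraction_unlabeled: float = 0.8
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    params: LesionParams = field(default_factory=LesionParams)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full self-training run needs, validated on load."""

    seed: int = 0
    target_size: int = 256
    paths: RunPaths = field(default_factory=RunPaths)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    augset_name: str = "simple"
    ratio_m: int = 4
    min_mask_pixels: int = 100
    binarize_threshold: float = 0.5
    synthetic: Optional[SyntheticConfig] = None

    def __post_init__(self) -> None:
        if self.target_size < 16:
            raise ConfigError("target_size must be >= 16")
        if self.ratio_m < 0:
            raise ConfigError("ratio_m must be >= 0")
        if self.min_mask_pixels < 0:
            raise ConfigError("min_mask_pixels must be >= 0")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ConfigError("binarize_threshold must be in (0, 1)")


_TUPLE_FIELDS = {
    "split_fractions",
    "area_fraction_range",
    "contrast_delta_range",
    "hair_count_range",
}
_NESTED_TUPLE_FIELDS = {"skin_tone_range", "lesion_tone_range"}


def _build(cls, data: dict, ctx: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{ctx}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{ctx}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub_ctx = f"{ctx}.{key}"
        if key == "paths":
            value = _build_paths(value, sub_ctx)
        elif key == "model":
            value = _build(ModelSpec, value, sub_ctx)
        elif key == "train":
            value = _build(TrainConfig, value, sub_ctx)
        elif key == "synthetic" and value is not None:
            value = _build(SyntheticConfig, value, sub_ctx)
        elif key == "params":
            value = _build(LesionParams, value, sub_ctx)
        elif key in _TUPLE_FIELDS:
            value = tuple(value)
        elif key in _NESTED_TUPLE_FIELDS:
            value = tuple(tuple(v) for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{ctx}: {exc}") from exc


def _build_paths(data: dict, ctx: str) -> RunPaths:
    if not isinstance(data, dict):
        raise ConfigError(f"{ctx}: expected a mapping")
    known = {f.name for f in fields(RunPaths)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{ctx}: unknown key(s) {sorted(unknown)}")
    kwargs = {k: (Path(v) if v is not None else None) for k, v in data.items()}
    return RunPaths(**kwargs)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    cfg = _build(RunConfig, data, ctx="run")
    return cfg


def dump_resolved_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration snapshot next to run outputs."""

    def _clean(obj):
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(asdict(cfg)), fh, sort_keys=True)
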