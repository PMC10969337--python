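"""Model specification, construction, prediction, and checkpointing.

The default architecture is :class:`~nsseg.nnet.CompactSegNet`; heavier
backbones can be plugged in by registering a builder under a new name with
:func:`register_builder` (an adapter hook — any object exposing
``predict_proba(NHWC) -> NHW`` and ``get_weights``/``set_weights`` works).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .nnet import CompactSegNet

__all__ = [
    "ModelSpec",
    "build_model",
    "register_builder",
    "predict_probability",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]

CHECKPOINT_VERSION = 1


class CheckpointError(IOError):
    """Checkpoint file is missing, corrupt, or version-incompatible."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; fully determines the initial weights."""

    depth: int = 3
    base_channels: int = 8
    use_aspp: bool = False
    skip_connections: bool = True
    dropout_p: float = 0.5
    seed: int = 0
    builder: str = "compact"

    def __post_init__(self) -> None:
        if not 2 <= self.depth <= 5:
            raise ValueError(f"depth must be in [2, 5], got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")


def _build_compact(spec: ModelSpec) -> CompactSegNet:
    return CompactSegNet(
        depth=spec.depth,
        base_channels=spec.base_channels,
        use_aspp=spec.use_aspp,
        skip_connections=spec.skip_connections,
        dropout_p=spec.dropout_p,
        seed=spec.seed,
    )


_BUILDERS: dict[str, Callable[[ModelSpec], object]] = {"compact": _build_compact}


def register_builder(name: str, fn: Callable[[ModelSpec], object]) -> None:
    """Register an alternative model builder selectable via ``spec.builder``."""
    _BUILDERS[name] = fn


def build_model(spec: ModelSpec):
    """Construct a model with deterministic, seed-derived initial weights."""
    try:
        builder = _BUILDERS[spec.builder]
    except KeyError:
        raise ValueError(f"unknown model builder {spec.builder!r}") from None
    model = builder(spec)
    model.spec = spec
    return model


def predict_probability(model, image: np.ndarray) -> np.ndarray:
    """Evaluation-mode per-pixel foreground probability for one H×W×3 image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got shape {image.shape}")
    if hasattr(model, "predict_proba"):
        prob = model.predict_proba(image[None].astype(np.float32))[0]
    elif callable(model):
        prob = np.asarray(model(image))
    else:
        raise TypeError(f"cannot predict with object of type {type(model)!r}")
    return prob.astype(np.float64)


def save_checkpoint(model, path, stage: str = "teacher", train_seed: int | None = None) -> None:
    """Write weights + spec + stage tag to a single-file .npz archive."""
    spec: ModelSpec = model.spec
    meta = {
        "version": CHECKPOINT_VERSION,
        "stage": stage,
        "train_seed": train_seed,
        "spec": asdict(spec),
    }
    weights = model.get_weights()
    arrays = {f"w{i:03d}": w for i, w in enumerate(weights)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; returns (model, stage_tag)."""
    path = Path(path)
    if not path.is_file():
        raise CheckpointError(f"checkpoint not found: {path}")
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {meta.get('version')} unsupported"
                )
            spec = ModelSpec(**meta["spec"])
            weights = [data[k] for k in sorted(data.files) if k.startswith("w")]
    except (KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
        if isinstance(exc, CheckpointError):
            raise
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
    model = build_model(spec)
    model.set_weights(weights)
    return model, meta["stage"]
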