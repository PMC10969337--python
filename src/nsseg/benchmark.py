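"""The synthetic self-training benchmark.

A scaled-down replication of the study design on generated dermoscopy-like
data: a small labeled training set, a much larger unlabeled pool, and a
held-out validation/test split, run through the full teacher → student →
student* loop. Default sizes (30 labeled / 20 val / 40 test / 240
unlabeled at 64×64, ratio m=4, 20 epochs per stage) keep a full run in the
minutes range on one CPU while preserving the labeled:unlabeled imbalance
that self-training targets.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .config import RunConfig, RunPaths, TrainConfig
from .datamodel import DatasetManifest
from .segmodel import ModelSpec
from .selftrain import SelfTrainResult, run_selftrain
from .synthetic import LesionParams, generate_dataset, strip_labels

__all__ = ["benchmark_config", "prepare_benchmark_data", "run_benchmark"]


def benchmark_config(
    out_dir,
    seed: int = 11,
    image_size: int = 64,
    epochs: int = 20,
    ratio_m: int = 4,
) -> RunConfig:
    """Run configuration of the synthetic benchmark."""
    return RunConfig(
        seed=seed,
        target_size=image_size,
        paths=RunPaths(out_dir=Path(out_dir)),
        model=ModelSpec(depth=3, base_channels=8, use_aspp=False,
                        skip_connections=True, dropout_p=0.5),
        train=TrainConfig(lr0=0.1, epochs=epochs, batch_size=10),
        augset_name="simple",
        ratio_m=ratio_m,
        min_mask_pixels=100,
        binarize_threshold=0.5,
    )


def prepare_benchmark_data(
    data_dir,
    seed: int,
    image_size: int = 64,
    n_labeled: int = 30,
    n_val: int = 20,
    n_test: int = 40,
    n_unlabeled: int = 240,
    params: LesionParams | None = None,
) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest, DatasetManifest]:
    """Generate the benchmark dataset; returns (labeled_train, val, test, pool)."""
    if params is None:
        params = LesionParams(image_size=image_size)
    else:
        params = replace(params, image_size=image_size)
    n_train = n_labeled + n_unlabeled
    n = n_train + n_val + n_test
    fractions = (n_train / n, n_val / n, n_test / n)
    manifest = generate_dataset(n, params, seed=seed, out_dir=data_dir,
                                split_fractions=fractions)
    labeled, pool = strip_labels(manifest, n_unlabeled / n_train, seed=seed)
    train_m = labeled.with_records([r for r in labeled if r.split == "train"])
    val_m = labeled.with_records([r for r in labeled if r.split == "val"])
    test_m = labeled.with_records([r for r in labeled if r.split == "test"])
    return train_m, val_m, test_m, pool


def run_benchmark(work_dir, seed: int = 11, **kwargs) -> SelfTrainResult:
    """Generate benchmark data under ``work_dir`` and run the full loop."""
    work_dir = Path(work_dir)
    cfg = benchmark_config(
        work_dir / "run",
        seed=seed,
        image_size=kwargs.pop("image_size", 64),
        epochs=kwargs.pop("epochs", 20),
        ratio_m=kwargs.pop("ratio_m", 4),
    )
    train_m, val_m, test_m, pool = prepare_benchmark_data(
        work_dir / "data", seed=seed, image_size=cfg.target_size, **kwargs
    )
    return run_selftrain(train_m, val_m, test_m, pool, cfg)
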