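"""Manifest-level training and the teacher → student → student* orchestrator.

:func:`train` loads a manifest into memory and delegates to
:class:`~nsseg.estimators.ConvSegmenter`. :func:`run_selftrain` runs the
full three-stage pipeline: train the teacher on labeled data only,
pseudo-label the unlabeled pool, screen and compose the student training
set at ratio m, train the noised student, regenerate pseudo-labels with the
best student, and train the student*. Every stage is evaluated on the
validation and test manifests (real labels only) and all randomness derives
from the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import RunConfig, TrainConfig, dump_resolved_config
from .datamodel import DatasetManifest, load_sample
from .estimators import ConvSegmenter, TrainHistory, cosine_lr
from .metrics import MetricsReport, ValidationPurityError, evaluate_model
from .pseudolabel import (
    CompositionSpec,
    PseudoLabelSet,
    compose_training_set,
    filter_by_area,
    generate_pseudolabels,
    scaled_min_pixels,
    write_rejection_log,
)
from .segmodel import ModelSpec, save_checkpoint
from .seeding import derive_seed

__all__ = ["cosine_lr", "TrainHistory", "SelfTrainResult", "train", "run_selftrain"]

logger = logging.getLogger("nsseg")

STAGES = ("teacher", "student", "student_star")


@dataclass
class SelfTrainResult:
    """Artifacts of a full self-training run."""

    checkpoints: dict[str, Path] = field(default_factory=dict)
    pseudo_sets: dict[str, PseudoLabelSet] = field(default_factory=dict)
    reports: dict[str, dict[str, MetricsReport]] = field(default_factory=dict)
    histories: dict[str, TrainHistory] = field(default_factory=dict)


def _load_arrays(manifest: DatasetManifest, require_mask: bool = True):
    images, masks = [], []
    for rec in manifest:
        img, mask = load_sample(rec, manifest.target_size)
        images.append(img)
        if require_mask:
            if mask is None:
                raise ValueError(f"record {rec.id!r} has no mask")
            masks.append(mask.values)
    X = np.stack(images)
    y = np.stack(masks) if require_mask else None
    return X, y


def train(
    spec: ModelSpec,
    train_set: DatasetManifest,
    val_set: DatasetManifest,
    cfg: TrainConfig,
):
    """Train one stage on a manifest; returns (network, history).

    The training set may mix real and pseudo provenance (augmentation noise
    is applied identically regardless); the validation set must contain
    only real-labeled records. The returned network carries the weights of
    the best-validation-mIoU epoch, not the last.
    """
    if len(train_set) == 0:
        raise ValueError("training manifest is empty")
    for rec in train_set:
        if rec.provenance == "unlabeled":
            raise ValueError(f"unlabeled record {rec.id!r} in training set")
    for rec in val_set:
        if rec.provenance != "real":
            raise ValidationPurityError(
                f"record {rec.id!r} with provenance {rec.provenance!r} in validation set"
            )
    X, y = _load_arrays(train_set)
    X_val, y_val = _load_arrays(val_set)
    est = ConvSegmenter(
        depth=spec.depth,
        base_channels=spec.base_channels,
        use_aspp=spec.use_aspp,
        skip_connections=spec.skip_connections,
        dropout_p=cfg.dropout_p,
        lr0=cfg.lr0,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        smooth=cfg.smooth,
        augmentations=cfg.augset_name,
        early_stop_patience=cfg.early_stop_patience,
        init_seed=spec.seed,
        random_state=cfg.seed,
    )
    est.fit(X, y, X_val, y_val)
    est.net_.spec = spec
    return est.net_, est.history_


def _check_disjoint(*manifests: DatasetManifest) -> None:
    seen: dict[str, str] = {}
    names = ("labeled_train", "val", "test", "unlabeled_pool")
    for name, manifest in zip(names, manifests):
        for rec in manifest:
            if rec.id in seen:
                raise ValueError(
                    f"sample id {rec.id!r} appears in both {seen[rec.id]} and {name}"
                )
            seen[rec.id] = name


def run_selftrain(
    labeled_train: DatasetManifest,
    val: DatasetManifest,
    test: DatasetManifest,
    unlabeled_pool: DatasetManifest,
    cfg: RunConfig,
) -> SelfTrainResult:
    """Run the full teacher → student → student* pipeline.

    Stage 1 trains the teacher on labeled data only (ratio m=0). Stage 2
    generates pseudo-labels with the teacher, screens masks below the
    (resolution-scaled) pixel threshold, composes the student set at ratio
    ``cfg.ratio_m``, and trains the student. Stage 3 regenerates
    pseudo-labels with the best student and trains the student*. All three
    stages share one architecture spec; each stage's init/train/composition
    seeds derive from ``cfg.seed``.
    """
    out_dir = Path(cfg.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dump_resolved_config(cfg, out_dir / "config_resolved.yaml")

    labeled_train = labeled_train.with_records(
        [r for r in labeled_train if r.split == "train"]
    )
    _check_disjoint(labeled_train, val, test, unlabeled_pool)
    min_px = scaled_min_pixels(cfg.min_mask_pixels, cfg.target_size)
    thr = cfg.binarize_threshold
    result = SelfTrainResult()

    def stage_cfg(stage: str) -> tuple[ModelSpec, TrainConfig]:
        spec = replace(cfg.model, seed=derive_seed(cfg.seed, stage, "init"))
        tc = replace(
            cfg.train,
            seed=derive_seed(cfg.seed, stage, "train"),
            augset_name=cfg.augset_name,
            dropout_p=cfg.train.dropout_p,
        )
        return spec, tc

    def run_stage(stage: str, train_set: DatasetManifest):
        spec, tc = stage_cfg(stage)
        logger.info("[%s] training on %d records", stage, len(train_set))
        model, history = train(spec, train_set, val, tc)
        ckpt = out_dir / f"{stage}.npz"
        save_checkpoint(model, ckpt, stage=stage, train_seed=tc.seed)
        result.checkpoints[stage] = ckpt
        result.histories[stage] = history
        result.reports[stage] = {
            "val": evaluate_model(model, val, threshold=thr),
            "test": evaluate_model(model, test, threshold=thr),
        }
        logger.info(
            "[%s] val mIoU=%.4f test mIoU=%.4f",
            stage,
            result.reports[stage]["val"].miou,
            result.reports[stage]["test"].miou,
        )
        return model

    teacher = run_stage("teacher", labeled_train)

    def pseudo_iteration(
        tag: str, generator_model, source_tag: str, stage: str
    ) -> DatasetManifest:
        pls = generate_pseudolabels(
            generator_model,
            unlabeled_pool,
            thr,
            out_dir / f"pseudo_{tag}",
            source_model_tag=source_tag,
        )
        pls = filter_by_area(pls, min_px)
        write_rejection_log(pls, out_dir / f"pseudo_{tag}_rejected.csv")
        logger.info(
            "[%s] pseudo-labels: %d kept, %d rejected (min %d px)",
            tag, len(pls.entries), len(pls.rejected), min_px,
        )
        result.pseudo_sets[tag] = pls
        comp = CompositionSpec(
            n_labeled=len(labeled_train),
            m=cfg.ratio_m,
            selection_seed=derive_seed(cfg.seed, stage, "compose"),
        )
        return compose_training_set(labeled_train, pls, comp)

    student_set = pseudo_iteration("iter1", teacher, "teacher", "student")
    student = run_stage("student", student_set)

    student_star_set = pseudo_iteration("iter2", student, "student", "student_star")
    run_stage("student_star", student_star_set)

    _write_metrics_json(result, out_dir / "metrics.json")
    return result


def _write_metrics_json(result: SelfTrainResult, path) -> None:
    payload = {
        stage: {split: rep.to_dict() for split, rep in by_split.items()}
        for stage, by_split in result.reports.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")
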