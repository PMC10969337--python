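"""Loss and evaluation suite: soft dice loss, pixel-wise confusion counts,
IoU/Dice/precision/recall, clinical-threshold fractions, bootstrap
confidence intervals, and test-time-augmentation evaluation.

Conventions (documented because they matter for degenerate synthetic data):
all four overlap metrics return 1 when their denominator is zero (the
both-empty case); the "fraction of images with IoU over τ" uses a strict
inequality; aggregates are arithmetic means of per-image values, never
dataset-pooled counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import augment as _augment
from .datamodel import DatasetManifest, as_mask_array, load_sample
from .seeding import derive_seed

__all__ = [
    "ConfusionCounts",
    "PerImageMetrics",
    "MetricsReport",
    "soft_dice_loss",
    "soft_dice_grad",
    "confusion_counts",
    "iou",
    "dice",
    "precision",
    "recall",
    "evaluate_model",
    "evaluate_masks",
    "fraction_above",
    "bootstrap_ci",
    "tta_evaluate",
    "ValidationPurityError",
    "CLINICAL_IOU_THRESHOLD",
]

# dermatologists judge segmentations with IoU above ~0.786 clinically useful
CLINICAL_IOU_THRESHOLD = 0.786
DEFAULT_THRESHOLDS = (0.8, CLINICAL_IOU_THRESHOLD)


class ValidationPurityError(ValueError):
    """A pseudo- or unlabeled record reached an evaluation code path."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise true/false positive/negative counts for one image."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerImageMetrics:
    id: str
    iou: float
    dice: float
    precision: float
    recall: float


@dataclass
class MetricsReport:
    """Per-image metrics plus their arithmetic-mean aggregates."""

    per_image: list[PerImageMetrics]
    miou: float
    mdice: float
    mprecision: float
    mrecall: float
    fraction_iou_above: dict[float, float] = field(default_factory=dict)
    ci: Optional[dict[str, tuple[float, float, float]]] = None

    def to_dict(self) -> dict:
        d = {
            "mIoU": self.miou,
            "mDice": self.mdice,
            "mPrecision": self.mprecision,
            "mRecall": self.mrecall,
            "fraction_iou_above": {str(k): v for k, v in self.fraction_iou_above.items()},
            "per_image": [
                {
                    "id": m.id,
                    "iou": m.iou,
                    "dice": m.dice,
                    "precision": m.precision,
                    "recall": m.recall,
                }
                for m in self.per_image
            ],
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    def per_image_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": m.id,
                    "iou": m.iou,
                    "dice": m.dice,
                    "precision": m.precision,
                    "recall": m.recall,
                }
                for m in self.per_image
            ]
        )


# ---------------------------------------------------------------------------
# Loss


def soft_dice_loss(prob: np.ndarray, target, smooth: float = 1.0) -> float:
    """Soft dice loss 1 − (2·Σp·y + λ)/(Σp + Σy + λ), sums over one image.

    Accepts a single H×W pair or N×H×W batches (mean of per-image losses).
    ``smooth`` is the λ smoothing parameter (default 1).
    """
    if smooth <= 0:
        raise ValueError("smoothing parameter must be positive")
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(as_mask_array(target) if not isinstance(target, np.ndarray) else target,
                        dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    if prob.ndim == 2:
        prob, target = prob[None], target[None]
    inter = (prob * target).sum(axis=(1, 2))
    denom = prob.sum(axis=(1, 2)) + target.sum(axis=(1, 2))
    losses = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return float(losses.mean())


def soft_dice_grad(prob: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    """Gradient of the batch-mean soft dice loss w.r.t. the probabilities."""
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.ndim == 2:
        prob, target = prob[None], target[None]
    n = prob.shape[0]
    inter = (prob * target).sum(axis=(1, 2), keepdims=True)
    denom = prob.sum(axis=(1, 2), keepdims=True) + target.sum(axis=(1, 2), keepdims=True)
    num = 2.0 * inter + smooth
    grad = -(2.0 * target * (denom + smooth) - num) / (denom + smooth) ** 2
    return grad / n


# ---------------------------------------------------------------------------
# Overlap metrics


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Exact pixel-wise confusion counts between two binary masks."""
    p = as_mask_array(pred).astype(bool)
    t = as_mask_array(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float:
    return 1.0 if den == 0 else num / den


def iou(c: ConfusionCounts) -> float:
    """Jaccard index TP/(TP+FP+FN); 1 when both masks are empty."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); 1 when both masks are empty."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def _per_image(id_: str, pred, truth) -> PerImageMetrics:
    c = confusion_counts(pred, truth)
    return PerImageMetrics(
        id=id_, iou=iou(c), dice=dice(c), precision=precision(c), recall=recall(c)
    )


def _aggregate(per_image: list[PerImageMetrics], thresholds=DEFAULT_THRESHOLDS) -> MetricsReport:
    if not per_image:
        raise ValueError("cannot aggregate an empty metrics list")
    ious = np.array([m.iou for m in per_image])
    report = MetricsReport(
        per_image=per_image,
        miou=float(ious.mean()),
        mdice=float(np.mean([m.dice for m in per_image])),
        mprecision=float(np.mean([m.precision for m in per_image])),
        mrecall=float(np.mean([m.recall for m in per_image])),
    )
    for tau in thresholds:
        report.fraction_iou_above[tau] = float(np.count_nonzero(ious > tau) / ious.size)
    return report


def fraction_above(report: MetricsReport, tau: float) -> float:
    """Fraction of images with per-image IoU strictly above tau."""
    if not report.per_image:
        raise ValueError("empty report")
    if not 0.0 < tau < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ious = np.array([m.iou for m in report.per_image])
    return float(np.count_nonzero(ious > tau) / ious.size)


# ---------------------------------------------------------------------------
# Model evaluation


def _as_predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    """Normalize a model handle into ``image (H,W,3) -> prob (H,W)``."""
    if hasattr(model, "predict_proba"):
        return lambda img: np.asarray(model.predict_proba(img[None].astype(np.float32)))[0]
    if callable(model):
        return model
    raise TypeError(f"cannot derive a prediction function from {type(model)!r}")


def _check_real(manifest: DatasetManifest) -> None:
    for rec in manifest:
        if rec.provenance != "real":
            raise ValidationPurityError(
                f"record {rec.id!r} has provenance {rec.provenance!r}; "
                "evaluation sets must contain only real-labeled records"
            )


def evaluate_model(model, manifest: DatasetManifest, threshold: float = 0.5) -> MetricsReport:
    """Predict every record, binarize at ``threshold`` (p ≥ threshold ⇒ 1),
    and score against the real ground-truth masks."""
    _check_real(manifest)
    predict = _as_predict_fn(model)
    per_image = []
    for rec in manifest:
        image, mask = load_sample(rec, manifest.target_size)
        prob = np.asarray(predict(image), dtype=np.float64)
        pred = (prob >= threshold).astype(np.uint8)
        per_image.append(_per_image(rec.id, pred, mask.values))
    return _aggregate(per_image)


def evaluate_masks(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> MetricsReport:
    """Score already-binarized (id, pred, truth) mask pairs."""
    return _aggregate([_per_image(i, p, t) for i, p, t in pairs])


# ---------------------------------------------------------------------------
# Bootstrap confidence interval


def bootstrap_ci(
    values, level: float = 0.95, reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need at least one value")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if reps < 100:
        warnings.warn(f"bootstrap with reps={reps} < 100 is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def attach_ci(report: MetricsReport, level: float = 0.95, reps: int = 10_000, seed: int = 0) -> MetricsReport:
    """Attach bootstrap CIs for each aggregate metric to a report."""
    report.ci = {}
    for name in ("iou", "dice", "precision", "recall"):
        vals = [getattr(m, name) for m in report.per_image]
        lo, hi = bootstrap_ci(vals, level=level, reps=reps, seed=derive_seed(seed, "ci", name))
        report.ci[name] = (lo, hi, level)
    return report


# ---------------------------------------------------------------------------
# Test-time augmentation


def tta_evaluate(
    model,
    manifest: DatasetManifest,
    ttaset: _augment.AugmentationSet,
    R: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Evaluate under R randomized augmentation runs and average per metric.

    Each run perturbs every (image, mask) pair with the set (geometric ops
    transform the mask too, keeping the pair aligned), evaluates, and the
    final report is the per-metric mean over runs.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    _check_real(manifest)
    predict = _as_predict_fn(model)
    run_reports: list[MetricsReport] = []
    for r in range(R):
        run_seed = derive_seed(seed, "tta_run", r)
        per_image = []
        for rec in manifest:
            image, mask = load_sample(rec, manifest.target_size)
            aug_img, aug_mask = _augment.apply(
                ttaset, image, mask.values, seed=derive_seed(run_seed, rec.id)
            )
            prob = np.asarray(predict(aug_img), dtype=np.float64)
            pred = (prob >= threshold).astype(np.uint8)
            per_image.append(_per_image(rec.id, pred, aug_mask))
        run_reports.append(_aggregate(per_image))
    return _mean_reports(run_reports)


def _mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    n = len(reports)
    if n == 1:
        return reports[0]
    ids = [m.id for m in reports[0].per_image]
    per_image = []
    for k, id_ in enumerate(ids):
        per_image.append(
            PerImageMetrics(
                id=id_,
                iou=float(np.mean([rep.per_image[k].iou for rep in reports])),
                dice=float(np.mean([rep.per_image[k].dice for rep in reports])),
                precision=float(np.mean([rep.per_image[k].precision for rep in reports])),
                recall=float(np.mean([rep.per_image[k].recall for rep in reports])),
            )
        )
    out = MetricsReport(
        per_image=per_image,
        miou=float(np.mean([rep.miou for rep in reports])),
        mdice=float(np.mean([rep.mdice for rep in reports])),
        mprecision=float(np.mean([rep.mprecision for rep in reports])),
        mrecall=float(np.mean([rep.mrecall for rep in reports])),
    )
    for tau in reports[0].fraction_iou_above:
        out.fraction_iou_above[tau] = float(
            np.mean([rep.fraction_iou_above[tau] for rep in reports])
        )
    return out
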