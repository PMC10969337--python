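"""Scikit-learn style estimators wrapping the segmentation network and the
Noisy Student self-training loop.

:class:`ConvSegmenter` is a fit/predict estimator around
:class:`~nsseg.nnet.CompactSegNet`: SGD with momentum and weight decay,
cosine-annealed learning rate, soft dice loss, per-sample input-noise
augmentation, spatial dropout as model noise, and best-validation-mIoU
checkpointing with early stopping.

:class:`NoisyStudentSegmenter` runs the three-stage teacher → student →
student* pipeline on in-memory arrays; the manifest/file-based orchestrator
in :mod:`nsseg.selftrain` builds on the same estimator.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone

from . import augment as _augment
from .metrics import soft_dice_grad, soft_dice_loss
from .nnet import CompactSegNet
from .pseudolabel import InsufficientPseudoPoolError, scaled_min_pixels
from .seeding import derive_seed

__all__ = ["ConvSegmenter", "NoisyStudentSegmenter", "TrainHistory", "cosine_lr"]

logger = logging.getLogger("nsseg")


def cosine_lr(epoch: int, total_epochs: int, lr0: float) -> float:
    """Cosine-annealed learning rate lr0·½(1 + cos(π·epoch/total))."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    if total_epochs == 0:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


@dataclass
class TrainHistory:
    """Per-epoch training trace plus the best-validation bookmark."""

    train_loss: list[float] = field(default_factory=list)
    val_miou: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_miou: float = float("nan")


def _mean_batch_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum(axis=(1, 2)).astype(np.float64)
    union = np.logical_or(pred, truth).sum(axis=(1, 2)).astype(np.float64)
    ious = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(ious.mean())


def _resolve_augset(augmentations) -> _augment.AugmentationSet:
    if augmentations is None:
        return _augment.named_set("none")
    if isinstance(augmentations, str):
        return _augment.named_set(augmentations)
    if isinstance(augmentations, _augment.AugmentationSet):
        return augmentations
    raise TypeError("augmentations must be a set name, an AugmentationSet, or None")


class ConvSegmenter(BaseEstimator):
    """Compact encoder–decoder lesion segmenter with a seeded SGD loop.

    Parameters mirror the training recipe: initial learning rate ``lr0``
    with cosine annealing over ``epochs``, ``momentum`` and
    ``weight_decay`` for SGD, ``batch_size``, dice-loss smoothing
    ``smooth``, spatial ``dropout_p`` before the classifier, and a named
    augmentation set applied per sample each epoch. The checkpoint kept is
    the one with the highest validation mIoU, with early stopping after
    ``early_stop_patience`` epochs without improvement.

    Attributes set by :meth:`fit`: ``net_`` (the trained network, best
    validation weights restored), ``history_`` (:class:`TrainHistory`),
    ``best_epoch_``, ``best_val_miou_``, ``n_iter_`` (epochs actually run).
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 8,
        use_aspp: bool = False,
        skip_connections: bool = True,
        dropout_p: float = 0.5,
        lr0: float = 0.1,
        momentum: float = 0.54,
        weight_decay: float = 0.01,
        batch_size: int = 10,
        epochs: int = 60,
        smooth: float = 1.0,
        augmentations: object = "simple",
        early_stop_patience: int = 15,
        binarize_threshold: float = 0.5,
        init_seed: int | None = None,
        random_state: int = 0,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.use_aspp = use_aspp
        self.skip_connections = skip_connections
        self.dropout_p = dropout_p
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.smooth = smooth
        self.augmentations = augmentations
        self.early_stop_patience = early_stop_patience
        self.binarize_threshold = binarize_threshold
        self.init_seed = init_seed
        self.random_state = random_state

    # -- validation ---------------------------------------------------------

    @staticmethod
    def _check_images(X: np.ndarray, name: str = "X") -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"{name} must be (n, H, W, 3), got {X.shape}")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError(f"{name} values must lie in [0, 1]")
        return X

    @staticmethod
    def _check_masks(y: np.ndarray, X: np.ndarray, name: str = "y") -> np.ndarray:
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"{name} must be (n, H, W) matching X, got {y.shape}")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError(f"{name} must be strictly binary")
        return y.astype(np.uint8)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images X (n,H,W,3 in [0,1]) and binary masks y (n,H,W)."""
        X = self._check_images(X)
        y = self._check_masks(y, X)
        if len(X) == 0:
            raise ValueError("training set is empty")
        have_val = X_val is not None and y_val is not None
        if have_val:
            X_val = self._check_images(X_val, "X_val")
            y_val = self._check_masks(y_val, X_val, "y_val")
        aset = _resolve_augset(self.augmentations)

        seed = self.random_state
        init_seed = self.init_seed if self.init_seed is not None else derive_seed(seed, "init")
        net = CompactSegNet(
            depth=self.depth,
            base_channels=self.base_channels,
            use_aspp=self.use_aspp,
            skip_connections=self.skip_connections,
            dropout_p=self.dropout_p,
            seed=init_seed,
        )
        velocities = [np.zeros_like(w) for w, _ in net.params()]
        history = TrainHistory()
        best_weights = net.get_weights()
        best_miou = -np.inf
        best_epoch = -1
        n = len(X)

        for epoch in range(self.epochs):
            lr = cosine_lr(epoch, self.epochs, self.lr0)
            order = np.random.default_rng(derive_seed(seed, "shuffle", epoch)).permutation(n)
            epoch_losses = []
            for step, start in enumerate(range(0, n, self.batch_size)):
                batch_idx = order[start : start + self.batch_size]
                imgs, masks = [], []
                for i in batch_idx:
                    img, msk = _augment.apply(
                        aset, X[i], y[i], seed=derive_seed(seed, "aug", epoch, int(i))
                    )
                    imgs.append(img)
                    masks.append(msk)
                xb = np.stack(imgs).astype(np.float32)
                yb = np.stack(masks).astype(np.float64)
                drop_rng = np.random.default_rng(derive_seed(seed, "dropout", epoch, step))
                prob = net.forward(xb, train=True, rng=drop_rng)
                epoch_losses.append(soft_dice_loss(prob, yb, smooth=self.smooth))
                net.zero_grad()
                net.backward(soft_dice_grad(prob.astype(np.float64), yb, smooth=self.smooth))
                for (w, g), v in zip(net.params(), velocities):
                    g_total = g + self.weight_decay * w
                    v *= self.momentum
                    v += g_total
                    w -= lr * v

            history.train_loss.append(float(np.mean(epoch_losses)))
            history.lr.append(lr)
            if have_val:
                val_miou = self._validate(net, X_val, y_val)
            else:
                val_miou = float("nan")
            history.val_miou.append(val_miou)
            logger.info(
                "epoch %d/%d loss=%.4f val_mIoU=%s lr=%.3g",
                epoch + 1,
                self.epochs,
                history.train_loss[-1],
                f"{val_miou:.4f}" if have_val else "n/a",
                lr,
            )
            improved = (have_val and val_miou > best_miou) or not have_val
            if improved:
                best_miou = val_miou if have_val else float("nan")
                best_epoch = epoch
                best_weights = net.get_weights()
            elif epoch - best_epoch >= self.early_stop_patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch + 1, best_epoch + 1)
                break

        net.set_weights(best_weights)
        history.best_epoch = best_epoch
        history.best_val_miou = best_miou if have_val else float("nan")
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_miou_ = history.best_val_miou
        self.n_iter_ = len(history.train_loss)
        return self

    def _validate(self, net: CompactSegNet, X_val, y_val, chunk: int = 16) -> float:
        ious = []
        for start in range(0, len(X_val), chunk):
            xb = X_val[start : start + chunk].astype(np.float32)
            prob = net.predict_proba(xb)
            pred = prob >= self.binarize_threshold
            ious.append(
                _mean_batch_iou(pred, y_val[start : start + chunk].astype(bool))
                * len(xb)
            )
        return float(np.sum(ious) / len(X_val))

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        self._require_fitted()
        X = self._check_images(X)
        out = []
        for start in range(0, len(X), 16):
            out.append(self.net_.predict_proba(X[start : start + 16].astype(np.float32)))
        return np.concatenate(out, axis=0).astype(np.float64)

    def predict(self, X) -> np.ndarray:
        """Binary masks thresholded at ``binarize_threshold``."""
        return (self.predict_proba(X) >= self.binarize_threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image IoU of thresholded predictions against y."""
        y = self._check_masks(np.asarray(y), self._check_images(X))
        return _mean_batch_iou(self.predict(X).astype(bool), y.astype(bool))

    def _require_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


class NoisyStudentSegmenter(BaseEstimator):
    """Three-stage Noisy Student self-training on in-memory arrays.

    fit() trains a teacher on the labeled data, pseudo-labels the unlabeled
    pool with it, screens small masks, composes a training set of
    n_labeled × m pseudo samples plus all labeled ones, trains a noised
    student, then repeats pseudo-labeling with the student to train the
    student*. The screening threshold ``min_mask_pixels`` is defined at
    256×256 and rescaled to the working resolution.

    Attributes: ``teacher_``, ``student_``, ``student_star_`` (fitted
    :class:`ConvSegmenter` instances), ``pseudo_kept_`` (per-iteration
    indices of kept pool entries), ``pseudo_selected_`` (indices actually
    trained on). Prediction delegates to the student*.
    """

    def __init__(
        self,
        segmenter: ConvSegmenter | None = None,
        ratio_m: int = 4,
        binarize_threshold: float = 0.5,
        min_mask_pixels: int = 100,
        random_state: int = 0,
    ):
        self.segmenter = segmenter
        self.ratio_m = ratio_m
        self.binarize_threshold = binarize_threshold
        self.min_mask_pixels = min_mask_pixels
        self.random_state = random_state

    def _stage_estimator(self, stage: str) -> ConvSegmenter:
        proto = self.segmenter if self.segmenter is not None else ConvSegmenter()
        est = clone(proto)
        est.set_params(random_state=derive_seed(self.random_state, stage, "train"))
        return est

    def fit(self, X, y, X_unlabeled, X_val=None, y_val=None):
        X = ConvSegmenter._check_images(X)
        y = ConvSegmenter._check_masks(np.asarray(y), X)
        X_unlabeled = ConvSegmenter._check_images(X_unlabeled, "X_unlabeled")
        min_px = scaled_min_pixels(self.min_mask_pixels, X.shape[1])

        logger.info("stage teacher: %d labeled samples", len(X))
        teacher = self._stage_estimator("teacher").fit(X, y, X_val, y_val)
        self.teacher_ = teacher

        current = teacher
        self.pseudo_kept_: dict[str, np.ndarray] = {}
        self.pseudo_selected_: dict[str, np.ndarray] = {}
        for stage in ("student", "student_star"):
            prob = current.predict_proba(X_unlabeled)
            masks = (prob >= self.binarize_threshold).astype(np.uint8)
            counts = masks.sum(axis=(1, 2))
            kept = np.flatnonzero(counts >= min_px)
            self.pseudo_kept_[stage] = kept
            needed = len(X) * self.ratio_m
            if len(kept) < needed:
                raise InsufficientPseudoPoolError(needed, len(kept))
            rng = np.random.default_rng(derive_seed(self.random_state, stage, "compose"))
            chosen = np.sort(rng.choice(kept, size=needed, replace=False))
            self.pseudo_selected_[stage] = chosen
            X_comb = np.concatenate([X, X_unlabeled[chosen]], axis=0)
            y_comb = np.concatenate([y, masks[chosen]], axis=0)
            perm = rng.permutation(len(X_comb))
            logger.info(
                "stage %s: %d labeled + %d pseudo (kept %d/%d)",
                stage, len(X), needed, len(kept), len(X_unlabeled),
            )
            est = self._stage_estimator(stage).fit(X_comb[perm], y_comb[perm], X_val, y_val)
            setattr(self, f"{stage}_", est)
            current = est
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.student_star_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.student_star_.predict(X)

    def score(self, X, y) -> float:
        return self.student_star_.score(X, y)
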