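"""Pseudo-label generation, area-based screening, and training-set
composition for self-training.

A trained model predicts masks for the unlabeled pool on clean
(un-augmented) images; probability maps are thresholded into binary masks
and written as PNGs. Masks whose foreground is smaller than a pixel
threshold are screened out (small or empty masks indicate low-confidence
predictions and hurt training). The student's training set is then the
labeled set plus exactly n_labeled × m pseudo-labeled samples drawn
uniformly without replacement from the kept pool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .datamodel import (
    DatasetManifest,
    SampleRecord,
    load_sample,
    save_mask,
)
from .segmodel import predict_probability

__all__ = [
    "PseudoLabelEntry",
    "RejectedEntry",
    "PseudoLabelSet",
    "CompositionSpec",
    "generate_pseudolabels",
    "filter_by_area",
    "compose_training_set",
    "scaled_min_pixels",
    "write_rejection_log",
    "LabeledRecordError",
    "InsufficientPseudoPoolError",
]

REFERENCE_SIZE = 256  # resolution at which the pixel threshold is defined


class LabeledRecordError(ValueError):
    """The unlabeled pool contained a labeled record."""


class InsufficientPseudoPoolError(ValueError):
    """Not enough kept pseudo-labels to satisfy the requested ratio."""

    def __init__(self, needed: int, available: int):
        self.needed = needed
        self.available = available
        self.shortfall = needed - available
        super().__init__(
            f"need {needed} pseudo-labels but only {available} kept "
            f"(shortfall {self.shortfall})"
        )


@dataclass(frozen=True)
class PseudoLabelEntry:
    id: str
    image_path: Path
    mask_path: Path
    foreground_count: int


@dataclass(frozen=True)
class RejectedEntry:
    id: str
    foreground_count: int
    reason: str


@dataclass
class PseudoLabelSet:
    """Kept and rejected pseudo-labels generated by one model."""

    source_model_tag: str
    threshold: float
    entries: list[PseudoLabelEntry] = field(default_factory=list)
    rejected: list[RejectedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pool_size(self) -> int:
        return len(self.entries) + len(self.rejected)


@dataclass(frozen=True)
class CompositionSpec:
    """Ratio-controlled student training-set composition."""

    n_labeled: int
    m: int
    selection_seed: int = 0
    selection: Literal["uniform", "confidence"] = "uniform"

    def __post_init__(self) -> None:
        if self.n_labeled < 1:
            raise ValueError("n_labeled must be >= 1")
        if self.m < 0:
            raise ValueError("ratio m must be >= 0")


def generate_pseudolabels(
    model,
    pool: DatasetManifest,
    threshold: float,
    out_dir,
    source_model_tag: str = "teacher",
) -> PseudoLabelSet:
    """Predict masks for every unlabeled record and write them as PNGs.

    Predictions use clean images (never augmented); each probability map is
    binarized at ``threshold`` (p ≥ threshold ⇒ foreground). Deterministic:
    the same model and pool produce byte-identical mask files.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pls = PseudoLabelSet(source_model_tag=source_model_tag, threshold=threshold)
    for rec in pool:
        if rec.provenance != "unlabeled":
            raise LabeledRecordError(
                f"record {rec.id!r} has provenance {rec.provenance!r}; "
                "the pseudo-label pool must be unlabeled"
            )
        image, _ = load_sample(rec, pool.target_size)
        prob = predict_probability(model, image)
        mask = (prob >= threshold).astype(np.uint8)
        mask_path = out_dir / f"{rec.id}_pseudo.png"
        save_mask(mask, mask_path)
        pls.entries.append(
            PseudoLabelEntry(
                id=rec.id,
                image_path=rec.image_path,
                mask_path=mask_path,
                foreground_count=int(mask.sum()),
            )
        )
    return pls


def filter_by_area(pls: PseudoLabelSet, min_pixels: int) -> PseudoLabelSet:
    """Screen out masks with foreground strictly below ``min_pixels``."""
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    kept: list[PseudoLabelEntry] = []
    rejected = list(pls.rejected)
    for entry in pls.entries:
        if entry.foreground_count < min_pixels:
            rejected.append(
                RejectedEntry(
                    id=entry.id,
                    foreground_count=entry.foreground_count,
                    reason="small_mask",
                )
            )
        else:
            kept.append(entry)
    return PseudoLabelSet(
        source_model_tag=pls.source_model_tag,
        threshold=pls.threshold,
        entries=kept,
        rejected=rejected,
    )


def scaled_min_pixels(min_pixels: int, target_size: int) -> int:
    """Rescale the screening threshold, defined at 256×256, to another
    working resolution (area scales quadratically)."""
    return int(round(min_pixels * (target_size / REFERENCE_SIZE) ** 2))


def compose_training_set(
    labeled: DatasetManifest, pseudo: PseudoLabelSet, spec: CompositionSpec
) -> DatasetManifest:
    """Combine all labeled records with n_labeled × m sampled pseudo-labels.

    The pseudo subset is a seeded uniform sample without replacement (or the
    top entries by foreground confidence proxy when selection="confidence");
    the combined order is shuffled with the same seed so training batches
    mix real and pseudo samples.
    """
    n_needed = spec.n_labeled * spec.m
    if len(pseudo.entries) < n_needed:
        raise InsufficientPseudoPoolError(n_needed, len(pseudo.entries))
    rng = np.random.default_rng(spec.selection_seed)
    if spec.selection == "confidence":
        order = sorted(
            range(len(pseudo.entries)),
            key=lambda i: (-pseudo.entries[i].foreground_count, pseudo.entries[i].id),
        )
        chosen = [pseudo.entries[i] for i in order[:n_needed]]
    else:
        idx = rng.choice(len(pseudo.entries), size=n_needed, replace=False)
        chosen = [pseudo.entries[i] for i in sorted(idx)]
    pseudo_records = [
        SampleRecord(
            id=e.id,
            image_path=e.image_path,
            mask_path=e.mask_path,
            provenance="pseudo",
            split="train",
        )
        for e in chosen
    ]
    combined = list(labeled.records) + pseudo_records
    perm = rng.permutation(len(combined))
    return DatasetManifest(
        records=[combined[i] for i in perm], target_size=labeled.target_size
    )


def write_rejection_log(pls: PseudoLabelSet, path) -> None:
    """CSV log of screened-out pseudo-labels (id, foreground_count, reason)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "foreground_count", "reason"])
        for rej in pls.rejected:
            writer.writerow([rej.id, rej.foreground_count, rej.reason])


def retag(pls: PseudoLabelSet, tag: str) -> PseudoLabelSet:
    return replace(pls, source_model_tag=tag)
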