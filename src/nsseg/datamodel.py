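"""Domain types and file I/O: sample manifests, images, binary masks.

A dataset is a CSV manifest indexing image files (RGB PNG/JPEG) and optional
single-channel mask PNGs. Images are loaded at a configurable square
``target_size`` with bilinear interpolation and scaled to [0, 1]; masks are
resized with nearest-neighbour sampling and binarized, so they never contain
gray values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger("nsseg")

Provenance = Literal["real", "pseudo", "unlabeled"]
Split = Literal["train", "val", "test"]

_PROVENANCES = ("real", "pseudo", "unlabeled")
_SPLITS = ("train", "val", "test")
MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "provenance", "split")


class ManifestError(ValueError):
    """Base class for manifest validation failures."""


class ManifestNotFoundError(ManifestError):
    """Manifest file does not exist."""


class MalformedRowError(ManifestError):
    """A manifest row has missing columns or illegal enum values."""


class DuplicateIdError(ManifestError):
    """Two manifest rows share the same sample id."""


class MaskConsistencyError(ManifestError):
    """Provenance and mask presence disagree (e.g. unlabeled with a mask)."""


class ImageLoadError(IOError):
    """An image or mask file is missing or unreadable."""


@dataclass(frozen=True)
class SampleRecord:
    """One indexed sample: an image with a real, pseudo, or absent mask."""

    id: str
    image_path: Path
    mask_path: Optional[Path]
    provenance: Provenance
    split: Split

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise MalformedRowError(
                f"record {self.id!r}: unknown provenance {self.provenance!r}"
            )
        if self.split not in _SPLITS:
            raise MalformedRowError(f"record {self.id!r}: unknown split {self.split!r}")
        if self.provenance == "unlabeled" and self.mask_path is not None:
            raise MaskConsistencyError(
                f"record {self.id!r}: unlabeled sample must not carry a mask"
            )
        if self.provenance in ("real", "pseudo") and self.mask_path is None:
            raise MaskConsistencyError(
                f"record {self.id!r}: {self.provenance} sample requires a mask path"
            )


@dataclass
class DatasetManifest:
    """Ordered collection of :class:`SampleRecord` with a loading resolution."""

    records: list[SampleRecord] = field(default_factory=list)
    target_size: int = 256

    def __post_init__(self) -> None:
        if self.target_size < 16:
            raise ValueError(f"target_size must be >= 16, got {self.target_size}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sample id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "DatasetManifest":
        wanted = set(ids)
        return DatasetManifest(
            records=[r for r in self.records if r.id in wanted],
            target_size=self.target_size,
        )

    def with_records(self, records: Sequence[SampleRecord]) -> "DatasetManifest":
        return DatasetManifest(records=list(records), target_size=self.target_size)


@dataclass
class BinaryMask:
    """A strictly binary H×W label grid with provenance bookkeeping."""

    values: np.ndarray
    provenance: Literal["real", "pseudo"] = "real"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {values.shape}")
        uniq = np.unique(values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be strictly binary {0,1}")
        self.values = values.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


def as_mask_array(mask) -> np.ndarray:
    """Return the uint8 {0,1} array behind a mask-like input."""
    if isinstance(mask, BinaryMask):
        return mask.values
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# Manifest I/O


def read_manifest(path, target_size: int = 256) -> DatasetManifest:
    """Read a CSV manifest; relative paths resolve against the manifest dir."""
    path = Path(path)
    if not path.is_file():
        raise ManifestNotFoundError(f"manifest not found: {path}")
    base = path.parent
    records: list[SampleRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != MANIFEST_COLUMNS:
            raise MalformedRowError(
                f"manifest header must be {','.join(MANIFEST_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(col) is None for col in MANIFEST_COLUMNS):
                raise MalformedRowError(f"{path}:{lineno}: missing column(s)")
            mask_raw = row["mask_path"].strip()
            records.append(
                SampleRecord(
                    id=row["id"].strip(),
                    image_path=_resolve(base, row["image_path"].strip()),
                    mask_path=_resolve(base, mask_raw) if mask_raw else None,
                    provenance=row["provenance"].strip(),
                    split=row["split"].strip(),
                )
            )
    return DatasetManifest(records=records, target_size=target_size)


def write_manifest(manifest: DatasetManifest, path) -> None:
    """Write a manifest as CSV; byte-stable for identical manifests."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for rec in manifest.records:
            writer.writerow(
                [
                    rec.id,
                    rec.image_path.as_posix(),
                    rec.mask_path.as_posix() if rec.mask_path else "",
                    rec.provenance,
                    rec.split,
                ]
            )


def _resolve(base: Path, raw: str) -> Path:
    p = Path(raw)
    return p if p.is_absolute() else (base / p)


# ---------------------------------------------------------------------------
# Image / mask loading


def nearest_resize(values: np.ndarray, out_size: int) -> np.ndarray:
    """Nearest-neighbour square resize by pixel-centre index sampling.

    Output pixel i samples input index floor((i + 0.5) * in / out), the
    standard index map; used for masks so values stay binary.
    """
    h, w = values.shape[:2]
    rows = np.minimum((np.arange(out_size) + 0.5) * h / out_size, h - 1).astype(int)
    cols = np.minimum((np.arange(out_size) + 0.5) * w / out_size, w - 1).astype(int)
    return values[np.ix_(rows, cols)]


def load_image(path, target_size: int) -> np.ndarray:
    """Load an RGB image, resize bilinearly, scale to [0, 1] float64."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (target_size, target_size):
                im = im.resize((target_size, target_size), Image.Resampling.BILINEAR)
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise ImageLoadError(f"cannot read image {path}: {exc}") from exc
    return arr


def load_mask_file(path, target_size: int, provenance: str = "real") -> BinaryMask:
    """Load a mask PNG, nearest-neighbour resize, binarize at >127."""
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            raw = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageLoadError(f"cannot read mask {path}: {exc}") from exc
    binary = (raw > 127).astype(np.uint8)
    if binary.shape != (target_size, target_size):
        binary = nearest_resize(binary, target_size)
    return BinaryMask(values=binary, provenance=provenance)


def load_sample(
    record: SampleRecord, target_size: int
) -> tuple[np.ndarray, Optional[BinaryMask]]:
    """Load one record's image (and mask, when present) at target_size."""
    image = load_image(record.image_path, target_size)
    mask: Optional[BinaryMask] = None
    if record.mask_path is not None:
        with Image.open(record.image_path) as im:
            image_size = im.size
        with Image.open(record.mask_path) as mm:
            mask_size = mm.size
        if mask_size != image_size:
            logger.warning(
                "record %s: mask size %s != image size %s; resizing mask to match",
                record.id,
                mask_size,
                image_size,
            )
        provenance = "pseudo" if record.provenance == "pseudo" else "real"
        mask = load_mask_file(record.mask_path, target_size, provenance=provenance)
    return image, mask


def save_mask(mask, path) -> None:
    """Write a binary mask as a single-channel {0,255} PNG (byte-stable)."""
    values = as_mask_array(mask)
    Image.fromarray((values * 255).astype(np.uint8), mode="L").save(path, format="PNG")


def retag(record: SampleRecord, **changes) -> SampleRecord:
    """Copy a record with some fields replaced (validation re-runs)."""
    return replace(record, **changes)
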