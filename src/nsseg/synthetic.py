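"""Seeded generator of dermoscopy-like images with exact ground-truth masks.

Each sample is a single darker, irregularly shaped lesion on a skin-toned
background. The lesion boundary is a radial-Fourier star region

    r(θ) = r0 · (1 + A · Σ_{j=1..k} a_j cos(jθ + φ_j)),   Σ a_j = 1,

whose base radius r0 is chosen in closed form so the rasterized foreground
fraction lands in the configured range. The image adds a sampled
skin/lesion contrast gap, a 2-px Gaussian-smoothed boundary, optional dark
hair-like polylines (occluders drawn on the image only, never the mask),
and i.i.d. Gaussian sensor noise.

The generator emulates the statistics that matter for the self-training
pipeline — lesion shape/size variation, irregular boundaries, low contrast,
occlusion — not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .datamodel import BinaryMask, DatasetManifest, SampleRecord, write_manifest

__all__ = [
    "LesionParams",
    "generate_sample",
    "generate_dataset",
    "strip_labels",
]

RGBRange = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class LesionParams:
    """Knobs of the synthetic dermoscopy image model (units: [0,1] intensity,
    fractions of image area/side)."""

    image_size: int = 256
    area_fraction_range: tuple[float, float] = (0.05, 0.40)
    contrast_delta_range: tuple[float, float] = (0.15, 0.45)
    boundary_harmonics: int = 6
    boundary_amplitude: float = 0.25
    noise_sigma: float = 0.03
    hair_count_range: tuple[int, int] = (0, 5)
    skin_tone_range: RGBRange = ((0.70, 0.85), (0.52, 0.68), (0.42, 0.58))
    lesion_tone_range: RGBRange = ((0.30, 0.45), (0.18, 0.32), (0.12, 0.28))

    def __post_init__(self) -> None:
        for name in (
            "area_fraction_range",
            "contrast_delta_range",
            "hair_count_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo must be <= hi, got ({lo}, {hi})")
        for rng3 in (self.skin_tone_range, self.lesion_tone_range):
            for lo, hi in rng3:
                if lo > hi:
                    raise ValueError("tone range lo must be <= hi")
        if self.area_fraction_range[1] >= 0.9:
            raise ValueError("area_fraction hi must be < 0.9")
        if not 0.0 <= self.boundary_amplitude < 0.5:
            raise ValueError("boundary_amplitude must be in [0, 0.5)")
        if self.boundary_harmonics < 0:
            raise ValueError("boundary_harmonics must be >= 0")
        if self.contrast_delta_range[0] <= 2.0 * self.noise_sigma:
            raise ValueError(
                "contrast_delta lo must exceed 2×noise_sigma so lesions are "
                "statistically detectable"
            )
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")


def _sample_rgb(rng: np.random.Generator, rgb_range: RGBRange) -> np.ndarray:
    return np.array([rng.uniform(lo, hi) for lo, hi in rgb_range])


def _star_mask(
    size: int,
    center: tuple[float, float],
    r0: float,
    amp: float,
    coeffs: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    dy, dx = rr - center[0], cc - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = np.full_like(dist, r0)
    if coeffs.size:
        pert = np.zeros_like(theta)
        for j, (a, phi) in enumerate(zip(coeffs, phases), start=1):
            pert += a * np.cos(j * theta + phi)
        boundary = r0 * (1.0 + amp * pert)
    return (dist <= boundary).astype(np.uint8)


def generate_sample(params: LesionParams, seed: int) -> tuple[np.ndarray, BinaryMask]:
    """Generate one (image, mask) pair; bitwise deterministic in (params, seed)."""
    rng = np.random.default_rng(seed)
    size = params.image_size
    k, amp = params.boundary_harmonics, params.boundary_amplitude

    if k > 0 and amp > 0:
        raw = rng.uniform(0.2, 1.0, size=k)
        coeffs = raw / raw.sum()  # Σ a_j = 1 bounds the radial perturbation by amp
        phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    else:
        coeffs = np.empty(0)
        phases = np.empty(0)

    af_lo, af_hi = params.area_fraction_range
    target_af = rng.uniform(af_lo, af_hi)
    # closed-form area of the star region: r0²·π·(1 + A²·Σa_j²/2)
    shape_factor = np.pi * (1.0 + amp**2 * float((coeffs**2).sum()) / 2.0)
    r0 = size * np.sqrt(target_af / shape_factor)

    margin = r0 * (1.0 + amp) + 2.0
    margin = min(margin, size / 2.0 - 1.0)
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)

    mask = _star_mask(size, (cy, cx), r0, amp, coeffs, phases)
    # correct quantization/clipping so the fraction lands inside the range
    for _ in range(8):
        frac = mask.mean()
        if af_lo <= frac <= af_hi:
            break
        r0 *= np.sqrt(np.clip(target_af / max(frac, 1e-9), 0.5, 2.0))
        mask = _star_mask(size, (cy, cx), r0, amp, coeffs, phases)

    skin = _sample_rgb(rng, params.skin_tone_range)
    lesion = _sample_rgb(rng, params.lesion_tone_range)
    delta = rng.uniform(*params.contrast_delta_range)
    # shift the lesion tone so the mean skin–lesion intensity gap equals delta
    lesion = np.clip(lesion + (skin.mean() - delta - lesion.mean()), 0.0, 1.0)

    field = gaussian_filter(mask.astype(np.float64), sigma=2.0)
    image = skin[None, None, :] + field[..., None] * (lesion - skin)[None, None, :]

    n_hairs = int(rng.integers(params.hair_count_range[0], params.hair_count_range[1] + 1))
    for _ in range(n_hairs):
        _draw_hair(image, rng)

    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return image, BinaryMask(values=mask, provenance="real")


def _draw_hair(image: np.ndarray, rng: np.random.Generator) -> None:
    """Darken an anti-aliased curved polyline, emulating a hair occluder."""
    size = image.shape[0]
    start = rng.uniform(0, size - 1, size=2)
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.3, 0.8) * size
    curvature = rng.uniform(-0.6, 0.6)
    n_seg = 8
    pts = [start]
    for i in range(n_seg):
        angle += curvature / n_seg
        step = length / n_seg
        pts.append(pts[-1] + step * np.array([np.sin(angle), np.cos(angle)]))
    strength = rng.uniform(0.3, 0.7)
    for a, b in zip(pts[:-1], pts[1:]):
        r0, c0 = int(round(a[0])), int(round(a[1]))
        r1, c1 = int(round(b[0])), int(round(b[1]))
        r0 = np.clip(r0, 0, size - 1)
        c0 = np.clip(c0, 0, size - 1)
        r1 = np.clip(r1, 0, size - 1)
        c1 = np.clip(c1, 0, size - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        image[rr, cc, :] *= (1.0 - strength * val)[:, None]


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    counts = [int(np.floor(n * f)) for f in fractions]
    remainder = n - sum(counts)
    i = 0
    while remainder > 0:  # distribute leftover samples train-first
        counts[i % 3] += 1
        remainder -= 1
        i += 1
    return tuple(counts)


def generate_dataset(
    n: int,
    params: LesionParams,
    seed: int,
    out_dir,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> DatasetManifest:
    """Write n image/mask PNG pairs plus a manifest CSV under ``out_dir``.

    Per-sample seeds are ``seed + index`` so any subset regenerates
    identically; split assignment is deterministic by index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    n_train, n_val, _ = _split_counts(n, split_fractions)
    records = []
    for idx in range(n):
        image, mask = generate_sample(params, seed + idx)
        sid = f"syn{idx:05d}"
        img_path = out_dir / "images" / f"{sid}.png"
        mask_path = out_dir / "masks" / f"{sid}.png"
        Image.fromarray(
            np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8), mode="RGB"
        ).save(img_path, format="PNG")
        Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(
            mask_path, format="PNG"
        )
        split = "train" if idx < n_train else ("val" if idx < n_train + n_val else "test")
        records.append(
            SampleRecord(
                id=sid,
                image_path=img_path,
                mask_path=mask_path,
                provenance="real",
                split=split,
            )
        )
    manifest = DatasetManifest(records=records, target_size=params.image_size)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def strip_labels(
    manifest: DatasetManifest, fraction_unlabeled: float, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Partition train records into a labeled set and an unlabeled pool.

    Unlabeled copies drop their mask path and get provenance "unlabeled";
    the ground truth stays on disk (and in the input manifest) purely for
    benchmarking pseudo-label quality — training code never sees it.
    Non-train records stay in the labeled manifest unchanged.
    """
    if not 0.0 < fraction_unlabeled < 1.0:
        raise ValueError("fraction_unlabeled must be in (0, 1)")
    train = [r for r in manifest.records if r.split == "train"]
    others = [r for r in manifest.records if r.split != "train"]
    n_unlab = int(round(fraction_unlabeled * len(train)))
    if n_unlab >= len(train):
        raise ValueError("fraction_unlabeled leaves zero labeled train records")
    rng = np.random.default_rng(seed)
    unlab_idx = set(rng.permutation(len(train))[:n_unlab].tolist())
    labeled_train, unlabeled = [], []
    for i, rec in enumerate(train):
        if i in unlab_idx:
            unlabeled.append(
                _dc_replace(rec, mask_path=None, provenance="unlabeled")
            )
        else:
            labeled_train.append(rec)
    labeled = DatasetManifest(
        records=labeled_train + others, target_size=manifest.target_size
    )
    pool = DatasetManifest(records=unlabeled, target_size=manifest.target_size)
    return labeled, pool
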