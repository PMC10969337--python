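"""Seeded image/mask augmentation engine (the pipeline's input noise).

Ops act jointly on an (image, mask) pair. Photometric ops never touch the
mask. Geometric ops sample one spatial transform, expressed as an inverse
coordinate map, and apply it to the image with bilinear interpolation and to
the mask with nearest-neighbour interpolation, so the pair can never
desynchronize. Out-of-frame samples are filled by reflection.

Named sets mirror the study design: a "simple" baseline (flips, rotation,
brightness/contrast/saturation, blur, hue shift) and four variants that add
one modern op each (coarse dropout, elastic transform, grid distortion,
optical distortion). A separate test-time-augmentation set adds shifts and
histogram equalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import exposure
from skimage.color import hsv2rgb, rgb2hsv

from .datamodel import BinaryMask, as_mask_array

__all__ = [
    "AugmentOp",
    "AugmentationSet",
    "named_set",
    "tta_set",
    "apply",
    "apply_with_trace",
    "NAMED_SETS",
]

PHOTOMETRIC = "photometric"
GEOMETRIC = "geometric"

# ---------------------------------------------------------------------------
# Parameter sampling, one function per op


def _sample_hflip(p, rng, shape):
    return {"axis": 1}


def _sample_vflip(p, rng, shape):
    return {"axis": 0}


def _grid(shape):
    h, w = shape
    return np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")


def _sample_rotation(p, rng, shape):
    lo, hi = p.get("angle_range", (-180.0, 180.0))
    angle = rng.uniform(lo, hi)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rad = np.deg2rad(angle)
    cos, sin = np.cos(rad), np.sin(rad)
    rr, cc = _grid(shape)
    dy, dx = rr - cy, cc - cx
    # inverse rotation of output coordinates back into the source frame
    src_r = cy + cos * dy + sin * dx
    src_c = cx - sin * dy + cos * dx
    return {"angle": angle, "coords": np.stack([src_r, src_c])}


def _sample_shift(p, rng, shape):
    frac = p.get("shift_frac", 0.1)
    h, w = shape
    dr = rng.uniform(-frac, frac) * h
    dc = rng.uniform(-frac, frac) * w
    rr, cc = _grid(shape)
    return {"dr": dr, "dc": dc, "coords": np.stack([rr - dr, cc - dc])}


def _sample_elastic(p, rng, shape):
    sigma = p.get("sigma", 8.0)
    alpha = p.get("alpha", 30.0)
    h, w = shape
    dr = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dc = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    rr, cc = _grid(shape)
    return {"coords": np.stack([rr + dr, cc + dc])}


def _axis_remap(n, steps, limit, rng):
    # perturb cell widths by ±limit, renormalize, then map output coordinate
    # to source coordinate piecewise-linearly
    widths = (n / steps) * (1.0 + rng.uniform(-limit, limit, steps))
    cum = np.concatenate([[0.0], np.cumsum(widths)])
    cum *= n / cum[-1]
    bounds_out = np.linspace(0.0, n, steps + 1)
    return np.interp(np.arange(n, dtype=np.float64), bounds_out, cum)


def _sample_grid(p, rng, shape):
    steps = p.get("num_steps", 5)
    limit = p.get("distort_limit", 0.3)
    h, w = shape
    map_r = _axis_remap(h, steps, limit, rng)
    map_c = _axis_remap(w, steps, limit, rng)
    rr = np.repeat(map_r[:, None], w, axis=1)
    cc = np.repeat(map_c[None, :], h, axis=0)
    return {"coords": np.stack([rr, cc])}


def _sample_optical(p, rng, shape):
    limit = p.get("distort_limit", 0.3)
    k = rng.uniform(-limit, limit)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc = _grid(shape)
    yn, xn = (rr - cy) / cy, (cc - cx) / cx
    factor = 1.0 + k * (xn * xn + yn * yn)
    return {"k": k, "coords": np.stack([cy + yn * factor * cy, cx + xn * factor * cx])}


def _sample_factor(key, default_range):
    def sampler(p, rng, shape):
        lo, hi = p.get(key, default_range)
        return {"factor": rng.uniform(lo, hi)}

    return sampler


def _sample_blur(p, rng, shape):
    lo, hi = p.get("sigma_range", (0.0, 1.5))
    return {"sigma": rng.uniform(lo, hi)}


def _sample_hue(p, rng, shape):
    lim = p.get("hue_limit", 0.05)
    return {"delta": rng.uniform(-lim, lim)}


def _sample_coarse_dropout(p, rng, shape):
    n_lo, n_hi = p.get("n_rect_range", (1, 8))
    s_lo, s_hi = p.get("side_frac_range", (0.02, 0.10))
    h, w = shape
    n = int(rng.integers(n_lo, n_hi + 1))
    rects = []
    for _ in range(n):
        rh = max(1, int(round(rng.uniform(s_lo, s_hi) * h)))
        rw = max(1, int(round(rng.uniform(s_lo, s_hi) * w)))
        r0 = int(rng.integers(0, max(1, h - rh)))
        c0 = int(rng.integers(0, max(1, w - rw)))
        rects.append((r0, c0, rh, rw))
    return {"rects": rects}


def _sample_hist_eq(p, rng, shape):
    return {}


# ---------------------------------------------------------------------------
# Image-side transforms


def _warp_image(image, sampled):
    coords = sampled["coords"]
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = map_coordinates(image[..., c], coords, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _flip_image(image, sampled):
    return np.flip(image, axis=sampled["axis"]).copy()


def _brightness(image, s):
    return np.clip(image * s["factor"], 0.0, 1.0)


def _contrast(image, s):
    mean = image.mean()
    return np.clip((image - mean) * s["factor"] + mean, 0.0, 1.0)


_LUMA = np.array([0.299, 0.587, 0.114])


def _saturation(image, s):
    gray = image @ _LUMA
    return np.clip(gray[..., None] + (image - gray[..., None]) * s["factor"], 0.0, 1.0)


def _hue_shift(image, s):
    hsv = rgb2hsv(np.clip(image, 0.0, 1.0))
    hsv[..., 0] = (hsv[..., 0] + s["delta"]) % 1.0
    return np.clip(hsv2rgb(hsv), 0.0, 1.0)


def _blur(image, s):
    if s["sigma"] <= 0:
        return image
    return np.clip(gaussian_filter(image, sigma=(s["sigma"], s["sigma"], 0)), 0.0, 1.0)


def _coarse_dropout(image, s):
    out = image.copy()
    for r0, c0, rh, rw in s["rects"]:
        out[r0 : r0 + rh, c0 : c0 + rw, :] = 0.0
    return out


def _hist_eq(image, s):
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = exposure.equalize_hist(image[..., c])
    return np.clip(out, 0.0, 1.0)


_SAMPLERS = {
    "h_flip": _sample_hflip,
    "v_flip": _sample_vflip,
    "rotation": _sample_rotation,
    "shift": _sample_shift,
    "elastic": _sample_elastic,
    "grid_distortion": _sample_grid,
    "optical_distortion": _sample_optical,
    "brightness": _sample_factor("factor_range", (0.8, 1.2)),
    "contrast": _sample_factor("factor_range", (0.8, 1.2)),
    "saturation": _sample_factor("factor_range", (0.8, 1.2)),
    "hue_shift": _sample_hue,
    "blur": _sample_blur,
    "coarse_dropout": _sample_coarse_dropout,
    "hist_eq": _sample_hist_eq,
}

_IMAGE_FNS = {
    "h_flip": _flip_image,
    "v_flip": _flip_image,
    "rotation": _warp_image,
    "shift": _warp_image,
    "elastic": _warp_image,
    "grid_distortion": _warp_image,
    "optical_distortion": _warp_image,
    "brightness": _brightness,
    "contrast": _contrast,
    "saturation": _saturation,
    "hue_shift": _hue_shift,
    "blur": _blur,
    "coarse_dropout": _coarse_dropout,
    "hist_eq": _hist_eq,
}

_GEOMETRIC_OPS = {
    "h_flip",
    "v_flip",
    "rotation",
    "shift",
    "elastic",
    "grid_distortion",
    "optical_distortion",
}


@dataclass(frozen=True)
class AugmentOp:
    """One augmentation operator with its firing probability and ranges."""

    name: str
    probability: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _SAMPLERS:
            raise ValueError(f"unknown augmentation op {self.name!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")

    @property
    def kind(self) -> str:
        return GEOMETRIC if self.name in _GEOMETRIC_OPS else PHOTOMETRIC

    def sample(self, rng: np.random.Generator, shape: tuple[int, int]) -> dict:
        """Draw this op's concrete parameters (incl. any coordinate map)."""
        return _SAMPLERS[self.name](self.params, rng, shape)

    def transform_image(self, image: np.ndarray, sampled: dict) -> np.ndarray:
        return _IMAGE_FNS[self.name](image, sampled)

    def transform_mask(self, mask: np.ndarray, sampled: dict) -> np.ndarray:
        """Apply the sampled spatial transform to a binary mask (identity for
        photometric ops)."""
        if self.kind == PHOTOMETRIC:
            return mask
        if "axis" in sampled:
            return np.flip(mask, axis=sampled["axis"]).copy()
        warped = map_coordinates(
            mask.astype(np.uint8), sampled["coords"], order=0, mode="reflect"
        )
        return (warped > 0).astype(np.uint8)


@dataclass(frozen=True)
class AugmentationSet:
    """Named, ordered list of augmentation operators."""

    name: str
    ops: tuple[AugmentOp, ...]


def _simple_ops() -> list[AugmentOp]:
    return [
        AugmentOp("h_flip", probability=0.5),
        AugmentOp("v_flip", probability=0.5),
        AugmentOp("rotation", probability=1.0),
        AugmentOp("brightness", probability=1.0),
        AugmentOp("contrast", probability=1.0),
        AugmentOp("saturation", probability=1.0),
        AugmentOp("blur", probability=0.5),
        AugmentOp("hue_shift", probability=1.0),
    ]


def _set_factory(extra: str | None):
    def factory() -> list[AugmentOp]:
        ops = _simple_ops()
        if extra is not None:
            ops.append(AugmentOp(extra, probability=0.5))
        return ops

    return factory


NAMED_SETS = {
    "none": lambda: [],
    "simple": _simple_ops,
    "simple+coarse_dropout": _set_factory("coarse_dropout"),
    "simple+elastic": _set_factory("elastic"),
    "simple+grid": _set_factory("grid_distortion"),
    "simple+optical": _set_factory("optical_distortion"),
}


def named_set(name: str) -> AugmentationSet:
    """Return one of the six study augmentation sets by name."""
    try:
        ops = NAMED_SETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown augmentation set {name!r}; choose from {sorted(NAMED_SETS)}"
        ) from None
    return AugmentationSet(name=name, ops=tuple(ops))


def tta_set() -> AugmentationSet:
    """Randomized perturbation set used for test-time-augmentation runs:
    flips, shifts, brightness/contrast, hue shift, histogram equalization,
    and rotation."""
    ops = (
        AugmentOp("h_flip", probability=0.5),
        AugmentOp("v_flip", probability=0.5),
        AugmentOp("shift", probability=0.5),
        AugmentOp("brightness", probability=1.0),
        AugmentOp("contrast", probability=1.0),
        AugmentOp("hue_shift", probability=1.0),
        AugmentOp("hist_eq", probability=0.5),
        AugmentOp("rotation", probability=1.0),
    )
    return AugmentationSet(name="tta", ops=ops)


def apply_with_trace(
    aset: AugmentationSet,
    image: np.ndarray,
    mask: Optional[np.ndarray | BinaryMask],
    seed: int,
):
    """Apply a set and return (image, mask, trace of fired (op, params))."""
    image = np.asarray(image, dtype=np.float64)
    mask_arr = None if mask is None else as_mask_array(mask)
    if mask_arr is not None and mask_arr.shape != image.shape[:2]:
        raise ValueError(
            f"image/mask size mismatch: {image.shape[:2]} vs {mask_arr.shape}"
        )
    rng = np.random.default_rng(seed)
    trace: list[tuple[AugmentOp, dict]] = []
    shape = image.shape[:2]
    for op in aset.ops:
        if rng.random() >= op.probability:
            continue
        sampled = op.sample(rng, shape)
        image = op.transform_image(image, sampled)
        if mask_arr is not None:
            mask_arr = op.transform_mask(mask_arr, sampled)
        trace.append((op, sampled))
    if mask is None:
        out_mask = None
    elif isinstance(mask, BinaryMask):
        out_mask = BinaryMask(values=mask_arr, provenance=mask.provenance)
    else:
        out_mask = mask_arr
    return image, out_mask, trace


def apply(
    aset: AugmentationSet,
    image: np.ndarray,
    mask: Optional[np.ndarray | BinaryMask],
    seed: int,
):
    """Apply a seeded augmentation set jointly to an image and optional mask."""
    image, out_mask, _ = apply_with_trace(aset, image, mask, seed)
    return image, out_mask
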