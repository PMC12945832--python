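"""Contrast enhancement, augmentation, and normalization.

Pipeline order is enforced by construction: the split happens first
(:mod:`glioscope.evaluation`), CLAHE is deterministic and per-image,
augmentation is applied to the training partition only, and
normalization statistics may come from the training partition only
(anything else raises :class:`~glioscope.errors.LeakageError`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, transform

from .errors import LeakageError

__all__ = [
    "ClaheParams",
    "clahe",
    "AugmentPolicy",
    "augment",
    "NormStats",
    "compute_norm_stats",
    "normalize",
    "resize_batch",
]

_NBINS = 256


@dataclass(frozen=True)
class ClaheParams:
    tile: int = 8
    clip_limit: float = 2.0

    def __post_init__(self):
        if self.tile < 1:
            raise ValueError("tile side must be a positive integer")
        if self.clip_limit <= 0:
            raise ValueError("clip limit must be positive")


def _value_range(image: np.ndarray, value_range):
    if value_range is not None:
        return float(value_range[0]), float(value_range[1])
    if image.dtype == np.uint8:
        return 0.0, 255.0
    if image.dtype == np.uint16:
        return 0.0, 65535.0
    return 0.0, 1.0


def _clip_histogram(hist: np.ndarray, clip: float) -> np.ndarray:
    """Clip bins at ``clip`` and redistribute the excess uniformly.

    Redistribution can push bins back over the limit, so iterate; the
    excess shrinks geometrically and a few rounds suffice.
    """
    hist = hist.astype(float)
    for _ in range(10):
        excess = np.sum(np.maximum(hist - clip, 0.0))
        if excess <= 1e-9:
            break
        hist = np.minimum(hist, clip)
        hist += excess / hist.size
    return np.minimum(hist, clip * (1.0 + 1e-6))


def clahe(image: np.ndarray, params: ClaheParams = ClaheParams(), value_range=None):
    """Contrast-limited adaptive histogram equalization of a 2-D image.

    Per-tile histograms (256 bins over the declared intensity range) are
    clipped at ``clip_limit`` times the uniform bin height, the excess is
    redistributed uniformly, and per-tile equalization mappings are
    blended bilinearly between tile centers.  The image is reflect-padded
    to a multiple of the tile size and cropped back.  Output has the
    input's dtype and intensity range.  Deterministic; idempotence is not
    claimed.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("clahe expects a single-channel 2-D image")
    t = params.tile
    if image.shape[0] < t or image.shape[1] < t:
        raise ValueError(
            f"image {image.shape} is smaller than one {t}x{t} tile"
        )
    lo, hi = _value_range(image, value_range)
    h, w = image.shape

    # quantize to 256 gray bins
    q = np.clip(np.rint((image.astype(float) - lo) / (hi - lo) * (_NBINS - 1)), 0, _NBINS - 1).astype(np.int64)

    # reflect-pad to tile multiples
    ph = (-h) % t
    pw = (-w) % t
    qp = np.pad(q, ((0, ph), (0, pw)), mode="reflect" if max(ph, pw) else "constant")
    hp, wp = qp.shape
    nth, ntw = hp // t, wp // t

    # per-tile clipped equalization lookup tables
    tiles = qp.reshape(nth, t, ntw, t).transpose(0, 2, 1, 3).reshape(nth, ntw, t * t)
    clip = params.clip_limit * (t * t) / _NBINS
    luts = np.empty((nth, ntw, _NBINS))
    for i in range(nth):
        for j in range(ntw):
            hist = np.bincount(tiles[i, j], minlength=_NBINS)
            hist = _clip_histogram(hist, clip)
            cdf = np.cumsum(hist)
            luts[i, j] = cdf / cdf[-1] * (_NBINS - 1)

    # bilinear interpolation between the four surrounding tile mappings
    yy = (np.arange(hp) + 0.5) / t - 0.5
    xx = (np.arange(wp) + 0.5) / t - 0.5
    i0 = np.clip(np.floor(yy).astype(int), 0, nth - 1)
    j0 = np.clip(np.floor(xx).astype(int), 0, ntw - 1)
    i1 = np.minimum(i0 + 1, nth - 1)
    j1 = np.minimum(j0 + 1, ntw - 1)
    wy = np.clip(yy - np.floor(yy), 0.0, 1.0)
    wx = np.clip(xx - np.floor(xx), 0.0, 1.0)
    wy[yy < 0] = 0.0
    wy[yy > nth - 1] = 1.0
    wx[xx < 0] = 0.0
    wx[xx > ntw - 1] = 1.0

    I0, J0 = i0[:, None], j0[None, :]
    I1, J1 = i1[:, None], j1[None, :]
    WY, WX = wy[:, None], wx[None, :]
    out = (
        (1 - WY) * (1 - WX) * luts[I0, J0, qp]
        + (1 - WY) * WX * luts[I0, J1, qp]
        + WY * (1 - WX) * luts[I1, J0, qp]
        + WY * WX * luts[I1, J1, qp]
    )
    out = out[:h, :w] / (_NBINS - 1) * (hi - lo) + lo
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), lo, hi).astype(image.dtype)
    return out.astype(image.dtype, copy=False)


# --------------------------------------------------------------------------
# augmentation

_ALL_OPS = (
    "flip_h",
    "flip_v",
    "rotate",
    "crop",
    "zoom",
    "stretch",
    "sharpen",
    "blur",
    "brightness",
    "contrast",
    "color_jitter",
    "random_erase",
)


@dataclass(frozen=True)
class AugmentPolicy:
    """Subset of augmentation ops with parameter ranges; train-partition only."""

    ops: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.ops) - set(_ALL_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def _jitter_brightness(img, rng, frac=0.1):
    return img + rng.uniform(-frac, frac)


def _jitter_contrast(img, rng, frac=0.1):
    m = img.mean()
    return (img - m) * (1.0 + rng.uniform(-frac, frac)) + m


def _resize(img, shape):
    return transform.resize(img, shape, order=1, mode="reflect", anti_aliasing=False)


def _apply_op(op: str, img: np.ndarray, rng: np.random.Generator, params: dict):
    h, w = img.shape
    if op == "flip_h":
        return img[:, ::-1]
    if op == "flip_v":
        return img[::-1, :]
    if op == "rotate":
        limit = params.get("rotate_deg", 15.0)
        angle = rng.uniform(-limit, limit)
        return transform.rotate(img, angle, mode="reflect", preserve_range=True)
    if op == "crop":
        f = rng.uniform(params.get("crop_min", 0.8), 1.0)
        ch, cw = max(1, int(round(f * h))), max(1, int(round(f * w)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        return _resize(img[top : top + ch, left : left + cw], (h, w))
    if op == "zoom":
        f = rng.uniform(*params.get("zoom_range", (0.9, 1.1)))
        return _resize(_resize(img, (max(1, int(round(f * h))), max(1, int(round(f * w))))), (h, w))
    if op == "stretch":
        fy = rng.uniform(0.9, 1.1)
        fx = rng.uniform(0.9, 1.1)
        return _resize(_resize(img, (max(1, int(round(fy * h))), max(1, int(round(fx * w))))), (h, w))
    if op == "sharpen":
        return filters.unsharp_mask(img, radius=1.0, amount=rng.uniform(0.5, 1.5))
    if op == "blur":
        return filters.gaussian(img, sigma=rng.uniform(0.5, 1.5), preserve_range=True)
    if op == "brightness":
        return _jitter_brightness(img, rng)
    if op == "contrast":
        return _jitter_contrast(img, rng)
    if op == "color_jitter":  # grayscale: brightness + contrast jitter
        return _jitter_contrast(_jitter_brightness(img, rng), rng)
    if op == "random_erase":
        a = rng.uniform(*params.get("erase_area", (0.02, 0.1)))
        aspect = rng.uniform(0.5, 2.0)
        eh = max(1, min(h, int(round(np.sqrt(a * h * w * aspect)))))
        ew = max(1, min(w, int(round(np.sqrt(a * h * w / aspect)))))
        top = rng.integers(0, h - eh + 1)
        left = rng.integers(0, w - ew + 1)
        out = img.copy()
        out[top : top + eh, left : left + ew] = rng.uniform(0.0, 1.0, size=(eh, ew))
        return out
    raise ValueError(f"unknown augmentation op {op!r}")


def augment(image, label, policy: AugmentPolicy, rng: np.random.Generator | None = None):
    """Apply the policy's op chain to one image; the label never changes.

    Geometry ops preserve the image size.  An empty policy is the identity.
    """
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    img = np.asarray(image, dtype=float)
    for op in policy.ops:
        img = _apply_op(op, img, rng, policy.params)
    return np.clip(img, 0.0, 1.0), label


# --------------------------------------------------------------------------
# normalization

_STD_EPS = 1e-8


@dataclass(frozen=True)
class NormStats:
    mean: float
    std: float
    source: str  # partition the statistics were computed on


def compute_norm_stats(images: np.ndarray, source: str = "train") -> NormStats:
    images = np.asarray(images, dtype=float)
    return NormStats(mean=float(images.mean()), std=float(images.std()), source=source)


def normalize(images: np.ndarray, stats: NormStats) -> np.ndarray:
    """(x - mean) / std with an epsilon floor on std.

    Refuses statistics whose provenance is not the training partition.
    """
    if stats.source != "train":
        raise LeakageError(
            f"normalization statistics must come from the training partition, "
            f"got source={stats.source!r}"
        )
    images = np.asarray(images, dtype=float)
    return (images - stats.mean) / max(stats.std, _STD_EPS)


def resize_batch(images: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    """Bilinear-resize a (N, H, W) stack to the model input size."""
    images = np.asarray(images, dtype=float)
    if images.shape[1:] == tuple(hw):
        return images
    return np.stack([_resize(im, hw) for im in images])
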