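"""Seeded synthetic T2-like phantom slices with two texture classes.

Each phantom is an elliptical head mask containing smooth background
structure and a single hyperintense lesion blob.  The two classes act as
molecular-subtype surrogates and differ in lesion texture and margin:

* class 0 — homogeneous lesion with a sharp margin;
* class 1 — heterogeneous lesion (band-passed noise texture) with an
  irregular margin built from low-order angular harmonics.

Global contrast is compressed and Gaussian (optionally Rician) noise is
added, so adaptive contrast enhancement has something real to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomImage", "make_phantom", "make_dataset", "texture_features"]


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 32
    n_classes: int = 2
    n_per_class: int = 300
    tumor_radius_frac: tuple[float, float] = (0.17, 0.26)
    # class-conditional lesion parameters (one entry per class)
    tumor_mean: tuple[float, ...] = (0.85, 0.73)
    tumor_texture_sigma: tuple[float, ...] = (0.02, 0.35)
    margin_sharpness: tuple[float, ...] = (0.6, 2.4)  # edge smoothing sigma (px)
    margin_irregularity: tuple[float, ...] = (0.02, 0.3)
    contrast_compression: float = 0.45
    noise_sigma: float = 0.02
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        for name in ("tumor_mean", "tumor_texture_sigma", "margin_sharpness", "margin_irregularity"):
            if len(getattr(self, name)) != self.n_classes:
                raise ValueError(f"{name} must have one entry per class")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomImage:
    raster: np.ndarray
    label: int
    patient_id: str
    tumor_mask: np.ndarray = field(repr=False, default=None)


def _smooth_noise(shape, rng, sigma):
    field_ = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(field_, sigma)
    field_ -= field_.mean()
    s = field_.std()
    return field_ / s if s > 0 else field_


def make_phantom(spec: PhantomSpec, class_idx: int, rng: np.random.Generator) -> PhantomImage:
    """Generate one phantom slice of the given class."""
    if not 0 <= class_idx < spec.n_classes:
        raise ValueError(f"class index {class_idx} out of range")
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = n / 2 + rng.uniform(-1, 1), n / 2 + rng.uniform(-1, 1)
    ay = n * rng.uniform(0.40, 0.46)
    ax = n * rng.uniform(0.34, 0.40)
    head = (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2) <= 1.0

    # smooth parenchyma background around mid-gray
    img = 0.42 + 0.06 * _smooth_noise((n, n), rng, sigma=n / 10)
    img += 0.03 * _smooth_noise((n, n), rng, sigma=n / 25)

    # lesion: radial mask with class-dependent angular irregularity
    r_t = n * rng.uniform(*spec.tumor_radius_frac)
    margin = min(0.38 * n - r_t, 0.3 * n)
    tcy = cy + rng.uniform(-margin, margin) * 0.8
    tcx = cx + rng.uniform(-margin, margin) * 0.8
    theta = np.arctan2(yy - tcy, xx - tcx)
    irr = spec.margin_irregularity[class_idx]
    radius = np.full_like(theta, r_t)
    for k in range(2, 6):
        radius += r_t * irr * rng.uniform(-1, 1) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    dist = np.hypot(yy - tcy, xx - tcx)
    tumor = (dist <= radius).astype(float)
    tumor = ndimage.gaussian_filter(tumor, spec.margin_sharpness[class_idx])
    tumor_mask = tumor > 0.5

    lesion = spec.tumor_mean[class_idx] + spec.tumor_texture_sigma[class_idx] * _smooth_noise(
        (n, n), rng, sigma=1.2
    )
    img = img * (1.0 - tumor) + lesion * tumor
    img = np.where(head, img, 0.02)

    # compress global contrast so adaptive equalization is non-trivial
    img = 0.5 + (img - 0.5) * spec.contrast_compression

    if spec.noise_model == "gaussian":
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    else:  # Rician magnitude noise
        re = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        im = rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.hypot(re, im)

    return PhantomImage(
        raster=np.clip(img, 0.0, 1.0),
        label=class_idx,
        patient_id="",
        tumor_mask=tumor_mask,
    )


def make_dataset(spec: PhantomSpec, out_dir: str | Path | None = None):
    """Generate a full phantom cohort.

    Returns ``(images, manifest)`` where ``images`` is an (N, size, size)
    float array and ``manifest`` a DataFrame with columns
    ``path, patient_id, label, split`` (split left empty until a splitter
    assigns it).  When ``out_dir`` is given, 8-bit PNGs and
    ``manifest.csv`` are also written there.
    """
    rng = np.random.default_rng(spec.seed)
    rasters, rows = [], []
    pid = 0
    for class_idx in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            ph = make_phantom(spec, class_idx, rng)
            pid += 1
            patient_id = f"P{pid:05d}"
            rasters.append(ph.raster)
            rows.append(
                {
                    "path": f"{patient_id}.png",
                    "patient_id": patient_id,
                    "label": class_idx,
                    "split": "",
                }
            )
    images = np.stack(rasters)
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, manifest.itertuples()):
            iio.imwrite(out_dir / row.path, (img * 255).round().astype(np.uint8))
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest


def texture_features(image: np.ndarray) -> np.ndarray:
    """Two hand-crafted lesion features: within-lesion variance and margin gradient.

    The lesion region is estimated as the brightest-quantile connected
    structure, so no ground-truth mask is needed.
    """
    img = np.asarray(image, dtype=float)
    thresh = np.quantile(img, 0.93)
    region = img >= thresh
    region = ndimage.binary_opening(region, iterations=1)
    if region.sum() < 9:
        region = img >= np.quantile(img, 0.9)
    inner = ndimage.binary_erosion(region, iterations=1)
    var_in = float(img[inner].var()) if inner.sum() > 4 else float(img[region].var())
    gy, gx = np.gradient(img)
    grad = np.hypot(gy, gx)
    border = region & ~inner
    margin_grad = float(grad[border].mean()) if border.any() else 0.0
    return np.array([var_in, margin_grad])
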