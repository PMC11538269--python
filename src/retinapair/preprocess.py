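"""Preprocessing and augmentation for fundus images and OCT volumes.

The canonical pipeline mirrors standard multi-modal retinal-imaging practice:
fundus images and OCT B-scans are converted to grayscale, bilinearly rescaled
to a common size (224x224 at shipping defaults), OCT volumes are reduced to
20 uniformly sampled B-scans in acquisition order, and each image/volume is
normalized to zero mean and unit variance as a whole.

Augmentations (used for the uni-modal self-supervised baselines, off by
default for the multi-modal objectives) follow the SimCLR family restricted
to transforms meaningful for grayscale retinal data: centered crop and
horizontal flip with probability 0.5 each, Gaussian blur and contrast
adjustment with probability 0.3 each.  Volumes are augmented slice-coherently
(one parameter draw applied to every B-scan) so 3D structure is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PreprocessConfig",
    "AugmentationPolicy",
    "to_grayscale",
    "resize",
    "subsample_slices",
    "normalize",
    "augment",
    "preprocess_fundus",
    "preprocess_volume",
]

ITU_R_601_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class PreprocessConfig:
    target_size: tuple[int, int] = (224, 224)
    n_keep_slices: int = 20
    grayscale_weights: tuple[float, float, float] = ITU_R_601_WEIGHTS
    normalize_eps: float = 1e-8

    def validate(self) -> None:
        if min(self.target_size) <= 0:
            raise ValueError("target_size must be positive")
        if self.n_keep_slices < 1:
            raise ValueError("n_keep_slices must be >= 1")


@dataclass
class AugmentationPolicy:
    p_crop: float = 0.5
    p_hflip: float = 0.5
    p_blur: float = 0.3
    p_contrast: float = 0.3
    crop_scale: tuple[float, float] = (0.8, 1.0)
    blur_sigma: tuple[float, float] = (0.1, 2.0)
    contrast_factor: tuple[float, float] = (0.6, 1.4)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("p_crop", "p_hflip", "p_blur", "p_contrast"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("crop_scale", "blur_sigma", "contrast_factor"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must satisfy lo <= hi")


def to_grayscale(image: np.ndarray, weights=ITU_R_601_WEIGHTS) -> np.ndarray:
    """Weighted channel sum; grayscale input is returned unchanged."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        return image @ np.asarray(weights, dtype=float)
    raise ValueError(f"expected 2-D or 3-channel image, got shape {image.shape}")


def resize(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize with half-pixel-center coordinates and edge clamping.

    An input already at the target size is returned value-identical.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("resize expects a nonempty 2-D grid")
    th, tw = target_size
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    h, w = image.shape

    def _axis(n_in: int, n_out: int):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        i0 = np.floor(src).astype(int)
        frac = src - i0
        lo = np.clip(i0, 0, n_in - 1)
        hi = np.clip(i0 + 1, 0, n_in - 1)
        return lo, hi, frac

    y0, y1, wy = _axis(h, th)
    x0, x1, wx = _axis(w, tw)
    top = (1 - wx) * image[np.ix_(y0, x0)] + wx * image[np.ix_(y0, x1)]
    bot = (1 - wx) * image[np.ix_(y1, x0)] + wx * image[np.ix_(y1, x1)]
    return (1 - wy)[:, None] * top + wy[:, None] * bot


def subsample_slices(n_slices: int, n_keep: int = 20) -> np.ndarray:
    """Ordered B-scan indices: ``round(linspace(0, n_slices - 1, n_keep))``.

    Always length ``n_keep``, non-decreasing, endpoints included.  When
    ``n_slices < n_keep`` the formula repeats indices.
    """
    if n_slices < 1 or n_keep < 1:
        raise ValueError("n_slices and n_keep must be >= 1")
    return np.rint(np.linspace(0, n_slices - 1, n_keep)).astype(int)


def normalize(array: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Whole-image/volume standardization: ``(x - mean) / max(sd, eps)``."""
    array = np.asarray(array, dtype=float)
    if not np.all(np.isfinite(array)):
        raise ValueError("normalize expects finite values")
    sd = array.std()
    return (array - array.mean()) / max(sd, eps)


def _center_crop_resize(img: np.ndarray, scale: float) -> np.ndarray:
    h, w = img.shape
    ch = max(1, int(round(scale * h)))
    cw = max(1, int(round(scale * w)))
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    return resize(img[r0 : r0 + ch, c0 : c0 + cw], (h, w))


def _adjust_contrast(img: np.ndarray, factor: float, mean: float) -> np.ndarray:
    return (img - mean) * factor + mean


def augment(
    sample: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the stochastic transform stack to a 2-D image or 3-D volume.

    Each transform fires independently with its policy probability.  For
    volumes, one parameter draw is shared by all slices.
    """
    policy.validate()
    sample = np.asarray(sample, dtype=float)
    if sample.ndim not in (2, 3):
        raise ValueError("augment expects a 2-D image or 3-D volume")

    do_crop = rng.random() < policy.p_crop
    crop_s = rng.uniform(*policy.crop_scale)
    do_flip = rng.random() < policy.p_hflip
    do_blur = rng.random() < policy.p_blur
    sigma = rng.uniform(*policy.blur_sigma)
    do_contrast = rng.random() < policy.p_contrast
    factor = rng.uniform(*policy.contrast_factor)

    is_volume = sample.ndim == 3
    slices = sample if is_volume else sample[None]
    out = []
    global_mean = float(sample.mean())
    for sl in slices:
        x = sl
        if do_crop:
            x = _center_crop_resize(x, crop_s)
        if do_flip:
            x = x[:, ::-1]
        if do_blur:
            x = gaussian_filter(x, sigma=sigma, mode="nearest")
        if do_contrast:
            x = _adjust_contrast(x, factor, global_mean)
        out.append(np.ascontiguousarray(x))
    result = np.stack(out, axis=0)
    return result if is_volume else result[0]


def preprocess_fundus(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Grayscale -> resize -> whole-image normalization."""
    config = config or PreprocessConfig()
    config.validate()
    img = to_grayscale(image, config.grayscale_weights)
    img = resize(img, config.target_size)
    return normalize(img, config.normalize_eps)


def preprocess_volume(volume: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Subsample B-scans in order -> resize each -> whole-volume normalization."""
    config = config or PreprocessConfig()
    config.validate()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume (slices, rows, cols)")
    idx = subsample_slices(volume.shape[0], config.n_keep_slices)
    resized = np.stack([resize(volume[i], config.target_size) for i in idx], axis=0)
    return normalize(resized, config.normalize_eps)
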