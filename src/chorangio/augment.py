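"""Weak and strong augmentation pipelines.

Weak augmentation (applied to every sample) is the geometric part: resize to a
square working size, then a random crop; masks ride along with the identical
transform using nearest-neighbor interpolation.  Strong augmentation (target
branch only) perturbs intensity: additive Gaussian noise, brightness/contrast
jitter (the grayscale reading of "color perturbation"), Gaussian smoothing and
a histogram shift, each applied with its own probability, output clipped to
[0, 1].  Masks are never strong-augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .data import BScan

__all__ = ["AugmentConfig", "weak_augment", "strong_augment"]


@dataclass(frozen=True)
class AugmentConfig:
    resize_to: int = 512
    crop_to: int = 448
    noise_sigma_range: tuple[float, float] = (0.01, 0.1)
    contrast_range: tuple[float, float] = (0.8, 1.25)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    smoothing_sigma_range: tuple[float, float] = (0.5, 1.5)
    hist_shift_fraction: float = 0.1
    p_noise: float = 0.5
    p_color: float = 0.5
    p_smooth: float = 0.5
    p_hist_shift: float = 0.5

    def __post_init__(self):
        if self.crop_to > self.resize_to:
            raise ValueError("crop_to must not exceed resize_to")


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img.astype(np.float32)
    return resize(img, (size, size), order=1, anti_aliasing=img.shape[0] > size,
                  preserve_range=True).astype(np.float32)


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    if mask.shape == (size, size):
        return mask.astype(np.uint8)
    out = resize(mask.astype(np.float32), (size, size), order=0,
                 anti_aliasing=False, preserve_range=True)
    return np.rint(out).astype(np.uint8)


def weak_augment(sample: BScan, config: AugmentConfig, rng: np.random.Generator) -> BScan:
    """Resize to `resize_to`^2 then random-crop to `crop_to`^2.

    The same geometric transform is applied to the image (bilinear) and any
    masks (nearest neighbor), so labels can never be invented.
    """
    img = _resize_image(sample.image, config.resize_to)
    span = config.resize_to - config.crop_to
    top = int(rng.integers(0, span + 1))
    left = int(rng.integers(0, span + 1))
    sl = (slice(top, top + config.crop_to), slice(left, left + config.crop_to))
    out = BScan(
        image=img[sl],
        domain_tag=sample.domain_tag,
        axial_spacing_um=sample.axial_spacing_um,
        lateral_spacing_mm=sample.lateral_spacing_mm,
    )
    if sample.vessel_mask is not None:
        out.vessel_mask = _resize_mask(sample.vessel_mask, config.resize_to)[sl]
    if sample.sublayer_mask is not None:
        out.sublayer_mask = _resize_mask(sample.sublayer_mask, config.resize_to)[sl]
    return out


def strong_augment(image: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Intensity perturbation stack for the target branch (FixMatch-style)."""
    out = np.asarray(image, dtype=np.float32).copy()
    if rng.random() < config.p_noise:
        sigma = rng.uniform(*config.noise_sigma_range)
        out = out + rng.normal(0.0, sigma, out.shape).astype(np.float32)
    if rng.random() < config.p_color:
        gain = rng.uniform(*config.contrast_range)
        offset = rng.uniform(*config.brightness_range)
        out = (out - 0.5) * gain + 0.5 + offset
    if rng.random() < config.p_smooth:
        sigma = rng.uniform(*config.smoothing_sigma_range)
        out = ndimage.gaussian_filter(out, sigma)
    if rng.random() < config.p_hist_shift:
        dyn = float(out.max() - out.min())
        out = out + rng.uniform(-1.0, 1.0) * config.hist_shift_fraction * dyn
    return np.clip(out, 0.0, 1.0).astype(np.float32)
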