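"""Patch sampling with foreground oversampling, and train-time augmentation.

Training operates on fixed-size patches cropped on the fly from the
preprocessed 2-channel volumes. To counter the extreme class imbalance
(new lesions occupy a vanishing fraction of the brain), the sampler
forces the patch center onto a foreground (new-lesion) voxel with
probability ``p_foreground`` (default 0.66), which guarantees that at
least that fraction of patches contains lesion voxels.

Spatial transforms (random affine, per-axis flips) use a single parameter
draw applied to image and label alike — trilinear for the image, nearest
for the label so masks stay binary. Intensity transforms (additive
Gaussian noise, Gaussian smoothing, scale/shift, smooth multiplicative
bias field, gamma contrast) touch the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter

__all__ = ["AugmentConfig", "PatchBatch", "sample_patch", "apply_affine",
           "random_affine", "random_flip", "intensity_transforms",
           "augment_patch"]


@dataclass
class AugmentConfig:
    """Sampler + augmentation parameters.

    Magnitudes are deliberately moderate defaults for z-scored FLAIR
    patches; every range and trigger probability is configurable.
    """

    p_foreground: float = 0.66
    patch_size: tuple[int, int, int] = (128, 128, 128)
    # spatial
    p_affine: float = 0.2
    rotation_deg: float = 15.0
    scale_frac: float = 0.10
    flip_p: tuple[float, float, float] = (0.5, 0.5, 0.5)
    # intensity, each gated by p_intensity
    p_intensity: float = 0.15
    noise_sd_range: tuple[float, float] = (0.01, 0.1)
    smooth_sigma_range: tuple[float, float] = (0.5, 1.5)
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    bias_amplitude: float = 0.3
    bias_degree: int = 3
    gamma_range: tuple[float, float] = (0.7, 1.5)
    seed: int = 0

    def __post_init__(self):
        probs = [self.p_foreground, self.p_affine, self.p_intensity,
                 *self.flip_p]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.noise_sd_range, self.smooth_sigma_range,
                       self.intensity_scale_range, self.intensity_shift_range,
                       self.gamma_range):
            if lo > hi:
                raise ValueError("augmentation ranges must be well-ordered")


@dataclass
class PatchBatch:
    images: np.ndarray                      # (B, 2, P, P, P)
    labels: np.ndarray                      # (B, 1, P, P, P), binary
    provenance: list = field(default_factory=list)  # (case_id, corner)


def _extract_padded(arr: np.ndarray, corner, size) -> np.ndarray:
    """Crop ``size`` starting at ``corner`` (may be out of bounds; zero-pad)."""
    out = np.zeros(arr.shape[:1] + tuple(size), dtype=arr.dtype)
    src, dst = [], []
    for c, p, n in zip(corner, size, arr.shape[1:]):
        lo, hi = max(c, 0), min(c + p, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - c, hi - c))
    out[(slice(None),) + tuple(dst)] = arr[(slice(None),) + tuple(src)]
    return out


def sample_patch(image: np.ndarray, mask: np.ndarray | None,
                 config: AugmentConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Draw one patch; foreground-centered with probability ``p_foreground``.

    ``image`` is (C, X, Y, Z); ``mask`` is (1, X, Y, Z) binary or None.
    Cases without foreground fall back to uniform sampling. Patches that
    cross the volume boundary are zero-padded. Returns (image patch,
    label patch, patch corner).
    """
    size = tuple(config.patch_size)
    shape = image.shape[1:]
    fg = None
    if mask is not None and mask.any():
        fg = np.argwhere(mask[0] > 0)
    if fg is not None and rng.random() < config.p_foreground:
        center = fg[rng.integers(len(fg))]
    else:
        center = np.array([rng.integers(n) for n in shape])
    corner = tuple(int(c - p // 2) for c, p in zip(center, size))
    img_patch = _extract_padded(image, corner, size)
    if mask is not None:
        lbl_patch = _extract_padded(mask, corner, size)
    else:
        lbl_patch = np.zeros((1,) + size, dtype=np.float32)
    return img_patch, lbl_patch, corner


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def apply_affine(image: np.ndarray, label: np.ndarray, angles_deg,
                 scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Rotate (per-axis angles) + isotropically scale image and label about
    the patch center with one shared transform; trilinear for the image,
    nearest for the label."""
    matrix = np.linalg.inv(_rotation_matrix(np.deg2rad(angles_deg)) * scale)
    center = (np.array(image.shape[1:]) - 1) / 2.0
    offset = center - matrix @ center
    img_out = np.stack([
        affine_transform(ch, matrix, offset=offset, order=1, mode="constant")
        for ch in image]).astype(image.dtype)
    lbl_out = np.stack([
        affine_transform(ch, matrix, offset=offset, order=0, mode="constant")
        for ch in label]).astype(label.dtype)
    return img_out, (lbl_out > 0.5).astype(label.dtype)


def random_affine(image: np.ndarray, label: np.ndarray,
                  config: AugmentConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One shared random rotation + isotropic scale about the patch center."""
    angles = rng.uniform(-config.rotation_deg, config.rotation_deg, size=3)
    s = rng.uniform(1.0 - config.scale_frac, 1.0 + config.scale_frac)
    return apply_affine(image, label, angles, s)


def random_flip(image: np.ndarray, label: np.ndarray, flip_p,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis flips; one decision per axis shared by image and label."""
    axes = [i + 1 for i, p in enumerate(flip_p) if rng.random() < p]
    if axes:
        image = np.flip(image, axis=axes).copy()
        label = np.flip(label, axis=axes).copy()
    return image, label


def _polynomial_bias(shape, degree, amplitude, rng) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape, dtype=np.float64)
    for a in range(degree + 1):
        for b in range(degree + 1 - a):
            for c in range(degree + 1 - a - b):
                if a == b == c == 0:
                    continue
                poly += rng.uniform(-amplitude, amplitude) * xx**a * yy**b * zz**c
    return np.exp(poly).astype(np.float32)


def intensity_transforms(image: np.ndarray, config: AugmentConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Apply each intensity transform with probability ``p_intensity``."""
    out = image.astype(np.float32, copy=True)
    spatial = out.shape[1:]
    if rng.random() < config.p_intensity:  # additive Gaussian noise
        sd = rng.uniform(*config.noise_sd_range)
        out += rng.normal(0.0, sd, out.shape).astype(np.float32)
    if rng.random() < config.p_intensity:  # Gaussian smoothing
        sigma = rng.uniform(*config.smooth_sigma_range)
        out = np.stack([gaussian_filter(ch, sigma) for ch in out])
    if rng.random() < config.p_intensity:  # scale + shift
        out = out * rng.uniform(*config.intensity_scale_range) \
            + rng.uniform(*config.intensity_shift_range)
    if rng.random() < config.p_intensity:  # multiplicative bias field
        out = out * _polynomial_bias(spatial, config.bias_degree,
                                     config.bias_amplitude, rng)
    if rng.random() < config.p_intensity:  # gamma contrast
        gamma = rng.uniform(*config.gamma_range)
        for c in range(out.shape[0]):
            lo, hi = out[c].min(), out[c].max()
            if hi - lo > 1e-8:
                out[c] = ((out[c] - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    return out


def augment_patch(image: np.ndarray, label: np.ndarray,
                  config: AugmentConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Full augmentation: gated affine, flips, then intensity transforms."""
    if rng.random() < config.p_affine:
        image, label = random_affine(image, label, config, rng)
    image, label = random_flip(image, label, config.flip_p, rng)
    image = intensity_transforms(image, config, rng)
    return image, label
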