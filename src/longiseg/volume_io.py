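"""NIfTI volume handling and the deterministic preprocessing chain.

The carrier type is :class:`Volume`: a channels-first scalar grid
(C, X, Y, Z) with a NIfTI affine and voxel spacing in mm. Longitudinal
inputs are pairs of co-registered FLAIR scans (baseline + follow-up) with
an optional binary new-lesion mask, bundled as :class:`LongitudinalCase`.

Preprocessing follows the fixed order: concatenate the two time points
into a 2-channel image -> crop to the minimal box containing nonzero
voxels -> channel-wise z-score -> resample to a common voxel size
(trilinear for images, nearest for masks). :class:`CropRecord` and
:func:`restore_to_original` invert the chain so predictions map back to
the native grid.

Conventions: 0-based half-open boxes; masks contain only {0, 1}; resampled
shapes use round-half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Volume", "LongitudinalCase", "CropRecord", "RegistrationError",
    "DegenerateInputError", "load_volume", "load_case", "save_volume",
    "concat_timepoints", "split_timepoints", "crop_foreground", "znormalize",
    "resample", "restore_to_original", "preprocess_case",
]

_AFFINE_TOL = 1e-3  # mm


class RegistrationError(ValueError):
    """Baseline/follow-up/mask grids disagree beyond tolerance."""


class DegenerateInputError(ValueError):
    """Input violates a precondition (all-zero volume, zero variance, ...)."""


@dataclass
class Volume:
    """Channels-first 3D scalar grid with world-space metadata."""

    data: np.ndarray          # (C, X, Y, Z)
    affine: np.ndarray        # 4x4 voxel-to-world, mm
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, X, Y, Z) grid, got {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.voxel_size, atol=_AFFINE_TOL):
            raise ValueError(
                f"affine scaling {col_norms} inconsistent with voxel_size "
                f"{self.voxel_size}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.voxel_size)


@dataclass
class LongitudinalCase:
    """One patient: co-registered baseline + follow-up, optional truth mask."""

    case_id: str
    baseline: Volume
    followup: Volume
    mask: Volume | None = None

    def __post_init__(self):
        vols = [self.baseline, self.followup] + ([self.mask] if self.mask else [])
        shapes = {v.spatial_shape for v in vols}
        if len(shapes) > 1:
            raise RegistrationError(f"grid shapes differ across volumes: {shapes}")
        for v in vols[1:]:
            if not np.allclose(v.affine, self.baseline.affine, atol=_AFFINE_TOL):
                raise RegistrationError("affines differ beyond tolerance; "
                                        "volumes are not co-registered")


@dataclass(frozen=True)
class CropRecord:
    """Half-open crop box enabling exact inversion of crop_foreground."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    def __post_init__(self):
        for lo, hi, n in zip(self.lower, self.upper, self.original_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"invalid crop box {self.lower}..{self.upper} "
                                 f"for shape {self.original_shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(np.linalg.norm(affine[:3, :3], axis=0))


def load_volume(path: str | Path, binarize: bool = False) -> Volume:
    """Read a 3D NIfTI file into a single-channel Volume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if binarize:
        data = (data > 0.5).astype(np.float32)
    affine = np.asarray(img.affine, dtype=float)
    return Volume(data[np.newaxis], affine, _voxel_size_from_affine(affine))


def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a single-channel Volume as a 3D NIfTI file, preserving the affine."""
    if volume.n_channels != 1:
        raise ValueError("only single-channel volumes can be written as 3D NIfTI")
    nib.save(nib.Nifti1Image(volume.data[0].astype(np.float32), volume.affine),
             str(path))


def load_case(baseline_path, followup_path, mask_path=None,
              case_id: str | None = None) -> LongitudinalCase:
    """Load a longitudinal FLAIR pair (and optional new-lesion mask)."""
    baseline = load_volume(baseline_path)
    followup = load_volume(followup_path)
    mask = load_volume(mask_path, binarize=True) if mask_path else None
    if case_id is None:
        case_id = Path(baseline_path).name.split(".")[0]
    return LongitudinalCase(case_id, baseline, followup, mask)


def concat_timepoints(case: LongitudinalCase) -> Volume:
    """Stack baseline (channel 0) and follow-up (channel 1) into a C=2 Volume."""
    return Volume(np.concatenate([case.baseline.data, case.followup.data], axis=0),
                  case.baseline.affine.copy(), case.baseline.voxel_size)


def split_timepoints(volume: Volume) -> tuple[Volume, Volume]:
    if volume.n_channels != 2:
        raise ValueError("expected a 2-channel volume")
    mk = lambda d: Volume(d[np.newaxis], volume.affine.copy(), volume.voxel_size)
    return mk(volume.data[0]), mk(volume.data[1])


def crop_foreground(volume: Volume, mask: Volume | None = None
                    ) -> tuple[Volume, Volume | None, CropRecord]:
    """Crop to the minimal box containing all voxels nonzero in any channel."""
    nz = np.any(volume.data != 0, axis=0)
    if not nz.any():
        raise DegenerateInputError("cannot crop an all-zero volume")
    idx = np.argwhere(nz)
    lower = tuple(int(v) for v in idx.min(axis=0))
    upper = tuple(int(v) + 1 for v in idx.max(axis=0))
    record = CropRecord(lower, upper, volume.spatial_shape)
    sl = (slice(None),) + record.slices
    out = Volume(volume.data[sl].copy(), volume.affine.copy(), volume.voxel_size)
    out_mask = None
    if mask is not None:
        out_mask = Volume(mask.data[sl].copy(), mask.affine.copy(), mask.voxel_size)
    return out, out_mask, record


def znormalize(volume: Volume) -> Volume:
    """Standardize each channel to zero mean / unit variance over all voxels."""
    data = volume.data.astype(np.float32, copy=True)
    for c in range(data.shape[0]):
        std = data[c].std()
        if std < 1e-8:
            raise DegenerateInputError(f"channel {c} has (near-)zero variance")
        data[c] = (data[c] - data[c].mean()) / std
    return Volume(data, volume.affine.copy(), volume.voxel_size)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def resample(volume: Volume, target_voxel, mode: str = "trilinear") -> Volume:
    """Resample to a new voxel size; trilinear for images, nearest for masks."""
    target_voxel = tuple(float(t) for t in target_voxel)
    if any(t <= 0 for t in target_voxel):
        raise ValueError(f"target voxel size must be positive, got {target_voxel}")
    in_shape = np.array(volume.spatial_shape, dtype=float)
    in_sp = np.array(volume.voxel_size)
    out_shape = _round_half_away(in_shape * in_sp / np.array(target_voxel))
    out_shape = tuple(int(max(1, n)) for n in out_shape)
    if out_shape == volume.spatial_shape and np.allclose(in_sp, target_voxel):
        return volume.copy()
    order = {"trilinear": 1, "nearest": 0}[mode]
    out = np.stack([
        _sk_resize(volume.data[c].astype(np.float32), out_shape, order=order,
                   mode="edge", anti_aliasing=False, preserve_range=True)
        for c in range(volume.n_channels)
    ]).astype(np.float32)
    if order == 0:
        vals = np.unique(volume.data)
        if vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0))):
            out = (out > 0.5).astype(np.float32)
    # direction vectors keep their orientation; column lengths become the new
    # spacing; the world position of voxel (0,0,0) is kept fixed.
    directions = volume.affine[:3, :3] / in_sp
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = directions * np.array(target_voxel)
    return Volume(out, new_affine, target_voxel)


def restore_to_original(pred: Volume, crop: CropRecord | None,
                        original_voxel, original_shape,
                        original_affine: np.ndarray | None = None,
                        mode: str = "trilinear") -> Volume:
    """Invert resampling (and cropping, if any) back onto the native grid.

    Voxels outside the crop box are zero. ``original_shape`` is the full
    native grid; when ``crop`` is given, the prediction is resampled to the
    crop box's shape and pasted into it.
    """
    original_voxel = tuple(float(t) for t in original_voxel)
    original_shape = tuple(int(n) for n in original_shape)
    if crop is not None and crop.original_shape != original_shape:
        raise ValueError("CropRecord inconsistent with original_shape")
    box_shape = (original_shape if crop is None else
                 tuple(hi - lo for lo, hi in zip(crop.lower, crop.upper)))
    order = {"trilinear": 1, "nearest": 0}[mode]
    box = np.stack([
        _sk_resize(pred.data[c].astype(np.float32), box_shape, order=order,
                   mode="edge", anti_aliasing=False, preserve_range=True)
        for c in range(pred.n_channels)
    ]).astype(np.float32)
    out = np.zeros((pred.n_channels,) + original_shape, dtype=np.float32)
    sl = (slice(None),) + (crop.slices if crop is not None
                           else tuple(slice(0, n) for n in original_shape))
    out[sl] = box
    if original_affine is None:
        directions = pred.affine[:3, :3] / np.array(pred.voxel_size)
        original_affine = pred.affine.copy()
        original_affine[:3, :3] = directions * np.array(original_voxel)
    return Volume(out, np.asarray(original_affine, dtype=float), original_voxel)


def preprocess_case(case: LongitudinalCase, target_voxel=(1.0, 1.0, 1.0),
                    crop: bool = True
                    ) -> tuple[Volume, Volume | None, CropRecord | None]:
    """Forward chain: concat -> (crop) -> z-score -> resample.

    Returns the preprocessed 2-channel image, the matching mask (if the case
    has one), and the CropRecord (None when ``crop`` is False).
    """
    image = concat_timepoints(case)
    mask = case.mask
    record = None
    if crop:
        image, mask, record = crop_foreground(image, mask)
    image = znormalize(image)
    image = resample(image, target_voxel, mode="trilinear")
    if mask is not None:
        mask = resample(mask, target_voxel, mode="nearest")
    return image, mask, record
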