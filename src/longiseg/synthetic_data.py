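"""Longitudinal FLAIR-like phantoms with stable and new lesions.

Each phantom case mimics the statistical structure of a co-registered
longitudinal FLAIR pair: a shared smooth background (sum of low-frequency
random harmonics), hyperintense *stable* lesions present at both time
points, hyperintense *new* lesions present only in the follow-up, a
per-time-point multiplicative gain and smooth bias field emulating scanner
differences, and additive Gaussian noise. The ground-truth mask marks new
lesions only. A dataset mixes in a configurable fraction of cases with no
new lesions at all, mirroring treated patients who remain stable
(about 11/40 in the cohort the defaults are modelled on).

Lesions are smoothed ellipsoids: simple enough for exact volume
bookkeeping, structured enough to exercise sampling, training, and the
lesion-wise evaluation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import LongitudinalCase, Volume, save_volume

__all__ = ["PhantomSpec", "GenerationError", "generate_case",
           "generate_dataset", "save_dataset", "load_dataset"]


class GenerationError(RuntimeError):
    """Raised when lesions cannot be placed within the retry budget."""


@dataclass
class PhantomSpec:
    """Parameters of one phantom case / dataset.

    lesion_contrast is expressed in units of the background field's spatial
    SD; the default of 8 puts lesions roughly 40% above mean background
    intensity — i.e., several SDs of the z-scored channel — matching the
    conspicuous hyperintensity of new white-matter lesions on FLAIR.
    timepoint_gain is the follow-up's global intensity scale relative to
    baseline (scanner/protocol drift); bias_amplitude is the relative
    amplitude of the follow-up's smooth multiplicative field.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_stable_lesions: int = 5
    n_new_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)  # mm (semi-axes)
    lesion_contrast: float = 8.0          # in background-SD units
    noise_sd: float = 0.02                # additive, intensity units
    bias_amplitude: float = 0.2           # relative, 0-1
    timepoint_gain: float = 1.1           # follow-up multiplicative gain
    frac_no_new_lesion: float = 11 / 40   # dataset-level case mix
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion radii must be positive and well-ordered")
        if not 0.0 <= self.frac_no_new_lesion <= 1.0:
            raise ValueError("frac_no_new_lesion must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _background(shape, rng, n_harmonics: int = 6) -> np.ndarray:
    """Smooth positive background: 1 + sum of low-frequency harmonics."""
    coords = [np.linspace(0.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    out = np.ones(shape, dtype=np.float32)
    for _ in range(n_harmonics):
        k = rng.integers(1, 4, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.02, 0.08)
        out += amp * (np.cos(2 * np.pi * k[0] * xx + phase[0])
                      * np.cos(2 * np.pi * k[1] * yy + phase[1])
                      * np.cos(2 * np.pi * k[2] * zz + phase[2])
                      ).astype(np.float32)
    return out


def _bias_field(shape, rng, amplitude: float) -> np.ndarray:
    """Multiplicative low-frequency field with mean ~1."""
    if amplitude <= 0:
        return np.ones(shape, dtype=np.float32)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    k = rng.uniform(0.5, 1.5, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    f = (np.cos(np.pi * k[0] * xx + phase[0])
         * np.cos(np.pi * k[1] * yy + phase[1])
         * np.cos(np.pi * k[2] * zz + phase[2])).astype(np.float32)
    return 1.0 + amplitude * f


def _ellipsoid_mask(shape, voxel_size, center_vox, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=np.float32)
    for g, c, s, a in zip(grids, center_vox, voxel_size, semi_axes_mm):
        r2 += (((g - c) * s) / a) ** 2
    return r2 <= 1.0


def _place_lesions(shape, voxel_size, n_lesions, radius_range, rng,
                   occupied: np.ndarray, max_retries: int = 100
                   ) -> list[np.ndarray]:
    """Place non-overlapping smoothed ellipsoids; returns their binary masks."""
    lo, hi = radius_range
    masks = []
    for _ in range(n_lesions):
        for attempt in range(max_retries):
            semi = rng.uniform(lo, hi, size=3)
            margin = [max(2, int(np.ceil(s / v)) + 1)
                      for s, v in zip(semi, voxel_size)]
            if any(2 * m >= n for m, n in zip(margin, shape)):
                continue
            center = [rng.integers(m, n - m) for m, n in zip(margin, shape)]
            mask = _ellipsoid_mask(shape, voxel_size, center, semi)
            if not mask.any() or (mask & occupied).any():
                continue
            occupied |= mask
            masks.append(mask)
            break
        else:
            raise GenerationError(
                f"could not place lesion after {max_retries} attempts")
    return masks


def _soft_profile(mask: np.ndarray) -> np.ndarray:
    """Unit-peak lesion profile with a smoothed one-voxel boundary rolloff."""
    from scipy.ndimage import gaussian_filter
    prof = gaussian_filter(mask.astype(np.float32), sigma=0.7)
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def generate_case(spec: PhantomSpec, rng: np.random.Generator,
                  case_id: str = "phantom") -> LongitudinalCase:
    """Generate one longitudinal phantom case.

    Baseline and follow-up share the background and stable lesions exactly;
    with noise_sd=0, bias_amplitude=0 and timepoint_gain=1 they differ only
    inside new lesions.
    """
    shape = tuple(spec.shape)
    bg = _background(shape, rng)
    sigma_bg = float(bg.std())
    occupied = np.zeros(shape, dtype=bool)
    stable = _place_lesions(shape, spec.voxel_size, spec.n_stable_lesions,
                            spec.lesion_radius_range, rng, occupied)
    new = _place_lesions(shape, spec.voxel_size, spec.n_new_lesions,
                         spec.lesion_radius_range, rng, occupied)

    amplitude = spec.lesion_contrast * sigma_bg
    shared = bg.copy()
    for m in stable:
        shared += amplitude * _soft_profile(m)
    baseline = shared.copy()
    followup = shared.copy()
    for m in new:
        followup += amplitude * _soft_profile(m)

    followup = followup * spec.timepoint_gain * _bias_field(
        shape, rng, spec.bias_amplitude)
    if spec.noise_sd > 0:
        baseline = baseline + rng.normal(0, spec.noise_sd, shape).astype(np.float32)
        followup = followup + rng.normal(0, spec.noise_sd, shape).astype(np.float32)

    mask = np.zeros(shape, dtype=np.float32)
    for m in new:
        mask[m] = 1.0

    affine = np.diag(list(spec.voxel_size) + [1.0])
    vol = lambda d: Volume(d.astype(np.float32)[np.newaxis], affine.copy(),
                           spec.voxel_size)
    return LongitudinalCase(case_id, vol(baseline), vol(followup), vol(mask))


def generate_dataset(n_cases: int, spec: PhantomSpec, seed: int | None = None
                     ) -> tuple[list[LongitudinalCase], pd.DataFrame]:
    """Generate a cohort with independent per-case RNG streams.

    A case is drawn with no new lesions with probability
    ``spec.frac_no_new_lesion``; otherwise it carries ``spec.n_new_lesions``.
    The manifest records the case id, new-lesion count, and total true
    new-lesion volume (mask voxels x voxel volume, mm^3).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if seed is None:
        seed = spec.seed
    streams = np.random.SeedSequence(seed).spawn(n_cases)
    voxel_volume = float(np.prod(spec.voxel_size))
    cases, rows = [], []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        no_new = rng.random() < spec.frac_no_new_lesion
        case_spec = replace(spec, n_new_lesions=0) if no_new else spec
        case = generate_case(case_spec, rng, case_id=f"case_{i:03d}")
        n_vox = int(case.mask.data.sum())
        rows.append({"case_id": case.case_id,
                     "n_new_lesions": case_spec.n_new_lesions,
                     "new_lesion_volume_mm3": n_vox * voxel_volume})
        cases.append(case)
    return cases, pd.DataFrame(rows)


def save_dataset(cases, manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """Write each case as a NIfTI triplet plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        d = out_dir / case.case_id
        d.mkdir(exist_ok=True)
        save_volume(case.baseline, d / "baseline.nii.gz")
        save_volume(case.followup, d / "followup.nii.gz")
        if case.mask is not None:
            save_volume(case.mask, d / "mask.nii.gz")
    manifest.to_csv(out_dir / "manifest.csv", index=False)


def load_dataset(data_dir: str | Path) -> list[LongitudinalCase]:
    """Load a directory of NIfTI triplets written by :func:`save_dataset`."""
    from .volume_io import load_case
    data_dir = Path(data_dir)
    cases = []
    for d in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        mask = d / "mask.nii.gz"
        cases.append(load_case(d / "baseline.nii.gz", d / "followup.nii.gz",
                               mask if mask.exists() else None, case_id=d.name))
    if not cases:
        raise IOError(f"no cases found under {data_dir}")
    return cases
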