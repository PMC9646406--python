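"""Full-volume prediction: sliding windows, aggregation, grid restoration.

A preprocessed 2-channel volume is tiled with fixed-size windows at 50%
overlap; window origins sit on a regular grid with stride
window x (1 - overlap), the final window clamped to the volume edge so
every voxel is covered at least once. Volumes smaller than the window are
zero-padded and un-padded afterwards. The per-voxel output is the
arithmetic mean of the softmax probabilities over all covering windows
(and, for an ensemble, over the member models), which keeps the class
probabilities on the simplex.

``predict_case`` runs the whole chain on a native-grid case: concatenate
time points -> z-score -> resample to 1 mm -> sliding-window (ensemble)
probabilities -> trilinear resample of the new-lesion probability back to
the native grid -> threshold at 0.5 (ties count as lesion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import (LongitudinalCase, Volume, concat_timepoints,
                        crop_foreground, restore_to_original, resample,
                        znormalize)

__all__ = ["InferenceConfig", "window_origins", "sliding_window_predict",
           "predict_case"]


@dataclass
class InferenceConfig:
    window: tuple[int, int, int] = (128, 128, 128)
    overlap: float = 0.5
    target_voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)
    threshold: float = 0.5
    crop: bool = False    # minimal-box crop before inference (off by default)

    def __post_init__(self):
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")


def window_origins(size: int, window: int, overlap: float) -> list[int]:
    """Regular-grid origins along one axis; last window clamped to the edge."""
    if size <= window:
        return [0]
    stride = max(1, int(round(window * (1.0 - overlap))))
    origins = list(range(0, size - window + 1, stride))
    if origins[-1] != size - window:
        origins.append(size - window)
    return origins


def sliding_window_predict(model, volume: np.ndarray, window=None,
                           overlap: float = 0.5) -> np.ndarray:
    """Mean-aggregated class probabilities over overlapping windows.

    ``model`` needs a ``predict_proba((1, C, w, w, w)) -> (1, J, w, w, w)``
    method; ``volume`` is (C, X, Y, Z). Returns (J, X, Y, Z).
    """
    volume = np.asarray(volume)
    if window is None:
        window = model.config.patch_size
    window = tuple(int(w) for w in window)
    shape = volume.shape[1:]
    pad = [max(0, w - n) for w, n in zip(window, shape)]
    if any(pad):
        volume = np.pad(volume, [(0, 0)] + [(0, p) for p in pad])
    padded_shape = volume.shape[1:]
    origins = [window_origins(n, w, overlap)
               for n, w in zip(padded_shape, window)]
    first = model.predict_proba(
        volume[np.newaxis, :, :window[0], :window[1], :window[2]])
    n_classes = first.shape[1]
    acc = np.zeros((n_classes,) + padded_shape, dtype=np.float64)
    count = np.zeros(padded_shape, dtype=np.int32)
    for ox in origins[0]:
        for oy in origins[1]:
            for oz in origins[2]:
                sl = (slice(ox, ox + window[0]), slice(oy, oy + window[1]),
                      slice(oz, oz + window[2]))
                if (ox, oy, oz) == (0, 0, 0):
                    probs = first
                else:
                    probs = model.predict_proba(
                        volume[(np.newaxis, slice(None)) + sl])
                acc[(slice(None),) + sl] += probs[0]
                count[sl] += 1
    out = acc / count
    crop_sl = tuple(slice(0, n) for n in shape)
    return out[(slice(None),) + crop_sl].astype(np.float32)


def predict_case(models, case: LongitudinalCase,
                 config: InferenceConfig | None = None) -> Volume:
    """End-to-end prediction of a binary new-lesion mask on the native grid."""
    if not isinstance(models, (list, tuple)):
        models = [models]
    config = config or InferenceConfig()
    native_shape = case.followup.spatial_shape
    native_voxel = case.followup.voxel_size
    native_affine = case.followup.affine

    image = concat_timepoints(case)
    record = None
    if config.crop:
        image, _, record = crop_foreground(image)
    image = znormalize(image)
    image = resample(image, config.target_voxel, mode="trilinear")

    probs = np.mean([
        sliding_window_predict(m, image.data, window=config.window,
                               overlap=config.overlap)
        for m in models], axis=0)
    fg = Volume(probs[1][np.newaxis], image.affine, image.voxel_size)
    fg_native = restore_to_original(fg, record, native_voxel, native_shape,
                                    original_affine=native_affine,
                                    mode="trilinear")
    mask = (fg_native.data >= config.threshold).astype(np.float32)
    return Volume(mask, np.asarray(native_affine, dtype=float), native_voxel)
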