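"""Deep-supervised Dice + focal segmentation loss.

The per-scale objective is L(G, P) = L_Dice(G, P) + L_Focal(G, P), with

* soft Dice   L_Dice = 1 - (2<G, P> + eps) / (||G||^2 + ||P||^2 + eps),
  the inner product and norms running jointly over all J x N entries
  (J classes, N voxels) of one patch;
* focal       L_Focal = -(1/N) <G, (1 - P)^gamma log P>, with gamma = 2
  down-weighting well-classified voxels.

Deep supervision sums the per-scale losses with weights
(lambda_0, lambda_1, lambda_2) = (1, 0.5, 0.25) over the full, 1/2 and 1/4
resolutions; lower-resolution ground truths are derived from the
full-resolution mask by nearest-neighbor striding (default; preserves the
one-hot structure) or 2x2x2 max-pooling (option; keeps one-voxel lesions
alive at coarse scales).

All loss functions accept autograd Tensors (gradients flow to P) or plain
arrays, operate on (B, J, ...) batches, and average over batch elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = ["LossConfig", "one_hot", "downsample_gt", "soft_dice_loss",
           "focal_loss", "combined_loss", "deep_supervision_loss"]

P_MIN = 1e-7  # probability clipping floor before log


@dataclass
class LossConfig:
    lambdas: tuple[float, ...] = (1.0, 0.5, 0.25)
    gamma: float = 2.0
    epsilon: float = 1e-5
    gt_downsample_mode: str = "nearest"   # or "maxpool"
    dice_mode: str = "joint"              # or "classwise"

    def __post_init__(self):
        if any(lam < 0 for lam in self.lambdas):
            raise ValueError("lambdas must be non-negative")
        if self.gamma < 0 or self.epsilon <= 0:
            raise ValueError("gamma must be >= 0 and epsilon > 0")
        if self.gt_downsample_mode not in ("nearest", "maxpool"):
            raise ValueError("gt_downsample_mode must be nearest or maxpool")
        if self.dice_mode not in ("joint", "classwise"):
            raise ValueError("dice_mode must be joint or classwise")


def one_hot(mask: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """(B, 1, ...) binary mask -> (B, J, ...) one-hot encoding."""
    mask = np.asarray(mask)
    labels = mask[:, 0].astype(np.int64)
    out = np.zeros((mask.shape[0], n_classes) + labels.shape[1:],
                   dtype=np.float32)
    for j in range(n_classes):
        out[:, j] = labels == j
    return out


def downsample_gt(mask: np.ndarray, factor: int, mode: str = "nearest"
                  ) -> np.ndarray:
    """Downsample a (B, 1, X, Y, Z) binary mask by an integer factor."""
    if factor == 1:
        return mask
    if mode == "nearest":
        return mask[:, :, ::factor, ::factor, ::factor]
    B, C, X, Y, Z = mask.shape
    blocks = mask.reshape(B, C, X // factor, factor, Y // factor, factor,
                          Z // factor, factor)
    return blocks.max(axis=(3, 5, 7))


def _pair(G, P) -> tuple[Tensor, Tensor]:
    P = P if isinstance(P, Tensor) else Tensor(np.asarray(P))
    G = G if isinstance(G, Tensor) else Tensor(np.asarray(G, dtype=P.dtype))
    if G.shape != P.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs P {P.shape}")
    return G, P


def _example_axes(t: Tensor) -> tuple[int, ...]:
    """Axes covering one example: all of a (J, N) pair, or all but the
    batch axis of a (B, J, spatial...) stack."""
    if t.data.ndim == 2:
        return (0, 1)
    return tuple(range(1, t.data.ndim))


def soft_dice_loss(G, P, epsilon: float = 1e-5, mode: str = "joint") -> Tensor:
    """Milletari-style soft Dice loss.

    ``mode="joint"`` (default) reduces jointly over all J x N entries;
    ``mode="classwise"`` computes one Dice per class and averages, which
    weights a rare foreground class equally with the background. The two
    coincide for a single class. Inputs are a single (J, N) example or a
    batched (B, J, spatial...) stack averaged over batch elements.
    """
    G, P = _pair(G, P)
    if mode == "joint":
        axes = _example_axes(P)
    elif mode == "classwise":
        axes = (1,) if P.data.ndim == 2 else tuple(range(2, P.data.ndim))
    else:
        raise ValueError("mode must be joint or classwise")
    inter = ag.tsum(ag.mul(G, P), axis=axes)
    norms = ag.add(ag.tsum(ag.power(G, 2.0), axis=axes),
                   ag.tsum(ag.power(P, 2.0), axis=axes))
    frac = ag.div(ag.add_const(ag.scale(inter, 2.0), epsilon),
                  ag.add_const(norms, epsilon))
    return ag.tmean(ag.add_const(ag.scale(frac, -1.0), 1.0))


def focal_loss(G, P, gamma: float = 2.0) -> Tensor:
    """Focal loss; N is the number of voxels per batch element."""
    G, P = _pair(G, P)
    n_vox = int(np.prod(P.shape[2:])) if P.data.ndim > 2 else P.shape[-1]
    Pc = ag.clip(P, P_MIN, 1.0 - P_MIN)
    weighted = ag.mul(G, ag.mul(ag.power(ag.add_const(ag.scale(Pc, -1.0), 1.0),
                                         gamma),
                                ag.log(Pc)))
    per_elem = ag.scale(ag.tsum(weighted, axis=_example_axes(P)), -1.0 / n_vox)
    return ag.tmean(per_elem)


def combined_loss(G, P, config: LossConfig | None = None) -> Tensor:
    """Sum of soft Dice and focal losses."""
    config = config or LossConfig()
    return ag.add(soft_dice_loss(G, P, config.epsilon, config.dice_mode),
                  focal_loss(G, P, config.gamma))


def deep_supervision_loss(pairs, config: LossConfig | None = None
                          ) -> tuple[Tensor, list[float]]:
    """Weighted multi-scale loss.

    ``pairs``: sequence of (G_i, P_i) ordered full -> coarser resolution.
    Returns (total loss Tensor, per-scale component values for logging).
    """
    config = config or LossConfig()
    if len(pairs) > len(config.lambdas):
        raise ValueError("more supervision pairs than lambda weights")
    total = None
    components = []
    for lam, (G, P) in zip(config.lambdas, pairs):
        if np.asarray(G.data if isinstance(G, Tensor) else G).shape != tuple(
                P.shape):
            raise ValueError("resolution mismatch between G_i and P_i")
        term = combined_loss(G, P, config)
        components.append(term.item())
        term = ag.scale(term, lam)
        total = term if total is None else ag.add(total, term)
    return total, components
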