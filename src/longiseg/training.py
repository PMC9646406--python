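"""Patch-based optimization, cross-validation folds, and fold ensembling.

Training draws a fresh batch of augmented patches at every step (no patch
caching), optimizes the deep-supervised Dice+focal objective with AdamW,
and anneals the learning rate to zero with a cosine schedule over the
fixed step budget. Reference settings: 100,000 steps, batch size 2,
initial lr 1e-5, weight decay 1e-2 — which on a 40-case cohort works out
to steps x batch / n_cases = 5,000 patches per subject. Desk-scale runs
shrink the network, patch size and step count but keep the procedure.

Checkpoints embed the model weights, optimizer moments, RNG state and
configs, so an interrupted run resumes bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from .augmentation import AugmentConfig, augment_patch, sample_patch
from .losses import LossConfig, deep_supervision_loss, downsample_gt, one_hot
from .network import NetworkConfig, UNet3D
from .volume_io import LongitudinalCase, preprocess_case

__all__ = ["TrainConfig", "TrainResult", "AdamW", "cosine_lr", "make_folds",
           "patches_per_subject", "train", "ensemble_predict",
           "save_train_checkpoint", "load_train_checkpoint"]


@dataclass
class TrainConfig:
    steps: int = 100_000
    batch_size: int = 2
    lr: float = 1e-5
    weight_decay: float = 1e-2
    seed: int = 0
    checkpoint_every: int = 0          # 0 = no periodic checkpoints
    n_folds: int = 5
    target_voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.steps < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("steps, batch_size must be >= 1 and lr > 0")


def patches_per_subject(steps: int, batch_size: int, n_cases: int) -> float:
    """Total patches seen per subject over a full schedule."""
    return steps * batch_size / n_cases


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """Cosine annealing from lr0 at step 0 to 0 at ``total_steps``."""
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * min(step, total_steps) / total_steps))


def make_folds(case_ids, n_folds: int, seed: int = 0) -> list[list[str]]:
    """Deterministic partition into near-equal validation folds."""
    case_ids = list(case_ids)
    if n_folds > len(case_ids):
        raise ValueError("more folds than cases")
    order = np.random.default_rng(seed).permutation(len(case_ids))
    return [[case_ids[i] for i in chunk]
            for chunk in np.array_split(order, n_folds)]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: dict[str, ag.Parameter], weight_decay: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            p.data = p.data - lr * (update + self.weight_decay * p.data)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}


@dataclass
class TrainResult:
    model: UNet3D
    log: list[dict] = field(default_factory=list)


def _prepare(dataset, target_voxel):
    prepared = []
    for case in dataset:
        image, mask, _ = preprocess_case(case, target_voxel=target_voxel,
                                         crop=True)
        m = mask.data if mask is not None else np.zeros(
            (1,) + image.spatial_shape, dtype=np.float32)
        prepared.append((case.case_id, image.data, m))
    return prepared


def _sample_batch(prepared, augment_config, rng, batch_size):
    images, labels = [], []
    for _ in range(batch_size):
        cid, image, mask = prepared[rng.integers(len(prepared))]
        img, lbl, _ = sample_patch(image, mask, augment_config, rng)
        img, lbl = augment_patch(img, lbl, augment_config, rng)
        images.append(img)
        labels.append(lbl)
    return np.stack(images), np.stack(labels)


def _loss_on_batch(model, images, labels, loss_config):
    logits = model.forward(images, training=True)
    pairs = []
    for i, lg in enumerate(logits):
        g = downsample_gt(labels, 2 ** i, loss_config.gt_downsample_mode)
        pairs.append((one_hot(g, model.config.n_classes),
                      ag.softmax(lg, axis=1)))
    return deep_supervision_loss(pairs, loss_config)


def train(model: UNet3D, dataset: list[LongitudinalCase],
          train_config: TrainConfig,
          loss_config: LossConfig | None = None,
          augment_config: AugmentConfig | None = None,
          start_step: int = 0,
          rng: np.random.Generator | None = None,
          optimizer: AdamW | None = None,
          checkpoint_path: str | Path | None = None) -> TrainResult:
    """Run ``train_config.steps`` optimization steps on freshly sampled patches.

    ``start_step``/``rng``/``optimizer`` support exact resumption from a
    checkpoint (see :func:`load_train_checkpoint`). Aborts on a non-finite
    loss with a diagnostic.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    loss_config = loss_config or LossConfig()
    if augment_config is None:
        augment_config = AugmentConfig(patch_size=model.config.patch_size)
    prepared = _prepare(dataset, train_config.target_voxel)
    rng = rng or np.random.default_rng(train_config.seed)
    optimizer = optimizer or AdamW(model.parameters,
                                   weight_decay=train_config.weight_decay)
    log: list[dict] = []
    for step in range(start_step, train_config.steps):
        lr = cosine_lr(step, train_config.steps, train_config.lr)
        images, labels = _sample_batch(prepared, augment_config, rng,
                                       train_config.batch_size)
        model.zero_grad()
        total, components = _loss_on_batch(model, images, labels, loss_config)
        if not np.isfinite(total.item()):
            raise RuntimeError(
                f"non-finite loss {total.item()} at step {step}; components "
                f"{components}")
        total.backward()
        optimizer.step(lr)
        log.append({"step": step, "lr": lr, "loss": total.item(),
                    "components": components})
        if (train_config.checkpoint_every and checkpoint_path
                and (step + 1) % train_config.checkpoint_every == 0):
            save_train_checkpoint(checkpoint_path, model, optimizer, rng,
                                  step + 1, train_config)
    return TrainResult(model=model, log=log)


def ensemble_predict(models, volume: np.ndarray, window=None,
                     overlap: float = 0.5) -> np.ndarray:
    """Voxelwise mean of the member models' sliding-window probability maps."""
    from .inference import sliding_window_predict
    if not models:
        raise ValueError("ensemble needs at least one model")
    n_classes = {m.config.n_classes for m in models}
    if len(n_classes) > 1:
        raise ValueError(f"ensemble members disagree on n_classes: {n_classes}")
    probs = [sliding_window_predict(m, volume, window=window, overlap=overlap)
             for m in models]
    return np.mean(probs, axis=0)


# ---------------------------------------------------------------------------
# resumable checkpoints
# ---------------------------------------------------------------------------

def _normalize(path) -> str:
    path = str(path)
    return path if path.endswith(".npz") else path + ".npz"


def save_train_checkpoint(path, model: UNet3D, optimizer: AdamW,
                          rng: np.random.Generator, step: int,
                          train_config: TrainConfig) -> None:
    payload = {}
    for k, p in model.parameters.items():
        payload[f"param/{k}"] = p.data
        payload[f"adam_m/{k}"] = optimizer.m[k]
        payload[f"adam_v/{k}"] = optimizer.v[k]
    meta = {"config": asdict(model.config),
            "train_config": asdict(train_config),
            "step": step,
            "adam_t": optimizer.t,
            "rng_state": rng.bit_generator.state}
    payload["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(_normalize(path), **payload)


def load_train_checkpoint(path) -> dict:
    """Rebuild model/optimizer/rng exactly as saved; returns a state dict."""
    with np.load(_normalize(path), allow_pickle=False) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        cfg = meta["config"]
        cfg["patch_size"] = tuple(cfg["patch_size"])
        model = UNet3D(NetworkConfig(**cfg))
        for k, p in model.parameters.items():
            p.data = archive[f"param/{k}"].copy()
        optimizer = AdamW(model.parameters,
                          weight_decay=meta["train_config"]["weight_decay"])
        optimizer.load_state({
            "t": meta["adam_t"],
            "m": {k: archive[f"adam_m/{k}"].copy() for k in model.parameters},
            "v": {k: archive[f"adam_v/{k}"].copy() for k in model.parameters}})
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    tc = meta["train_config"]
    for key in ("target_voxel",):
        tc[key] = tuple(tc[key])
    return {"model": model, "optimizer": optimizer, "rng": rng,
            "step": int(meta["step"]), "train_config": TrainConfig(**tc)}
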