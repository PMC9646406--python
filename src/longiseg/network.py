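"""U-shaped 3D segmentation networks with interchangeable blocks.

One shared encoder-decoder skeleton — a 3x3x3 stem, four resolution
levels whose channel width doubles with every 2x2x2 strided-conv
downsampling and halves with every 2x2x2 transposed-conv upsampling, skip
concatenation, and pointwise deep-supervision heads at the three highest
decoder resolutions — instantiated with one of three block families:

* ``plain``          : [conv3 -> GroupNorm -> LeakyReLU] x 2
* ``residual``       : conv3 -> GN -> LeakyReLU -> conv3 -> GN, shortcut
                       added between the last GN and the last LeakyReLU;
                       the shortcut is a pointwise conv when the block
                       changes width, identity otherwise
* ``preactivation``  : [GN -> LeakyReLU -> conv3] x 2 with the same
                       shortcut rule and no trailing activation

In training mode the forward pass returns the full-resolution logits plus
auxiliary logits at 1/2 and 1/4 resolution for deep supervision; in
inference mode only the full-resolution logits.

``count_parameters`` reproduces the trainable-scalar count from a
closed-form per-layer ledger, independent of building the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Parameter, Tensor

__all__ = ["NetworkConfig", "UNet3D", "build_network", "count_parameters",
           "parameter_ledger", "save_checkpoint", "load_checkpoint"]

_BLOCK_KINDS = ("plain", "residual", "preactivation")


@dataclass
class NetworkConfig:
    block_kind: str = "plain"
    in_channels: int = 2
    n_classes: int = 2
    n_levels: int = 4
    base_width: int = 64
    norm_group_size: int = 8
    leaky_slope: float = 0.01
    n_deep_supervision: int = 3
    patch_size: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self):
        if self.block_kind not in _BLOCK_KINDS:
            raise ValueError(f"block_kind must be one of {_BLOCK_KINDS}")
        if self.base_width % self.norm_group_size:
            raise ValueError("base_width must be divisible by norm_group_size")
        if self.n_deep_supervision > self.n_levels - 1:
            raise ValueError("n_deep_supervision must be <= n_levels - 1")
        stride = 2 ** (self.n_levels - 1)
        if any(p % stride for p in self.patch_size):
            raise ValueError(
                f"patch dims {self.patch_size} must be divisible by {stride}")

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(self.n_levels)]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Store:
    """Ordered name->Parameter registry shared by all layers of a model."""

    def __init__(self, rng: np.random.Generator, dtype):
        self.rng = rng
        self.dtype = dtype
        self.params: dict[str, Parameter] = {}

    def conv(self, name, c_in, c_out, k) -> tuple[Parameter, Parameter]:
        fan_in = c_in * k ** 3
        std = np.sqrt(2.0 / fan_in)  # He init for leaky-rectified nets
        w = Parameter(self.rng.normal(0, std, (c_out, c_in, k, k, k))
                      .astype(self.dtype))
        b = Parameter(np.zeros(c_out, dtype=self.dtype))
        self.params[f"{name}.weight"] = w
        self.params[f"{name}.bias"] = b
        return w, b

    def conv_t(self, name, c_in, c_out) -> tuple[Parameter, Parameter]:
        std = np.sqrt(2.0 / (c_in * 8))
        w = Parameter(self.rng.normal(0, std, (c_in, c_out, 2, 2, 2))
                      .astype(self.dtype))
        b = Parameter(np.zeros(c_out, dtype=self.dtype))
        self.params[f"{name}.weight"] = w
        self.params[f"{name}.bias"] = b
        return w, b

    def norm(self, name, c) -> tuple[Parameter, Parameter]:
        g = Parameter(np.ones(c, dtype=self.dtype))
        b = Parameter(np.zeros(c, dtype=self.dtype))
        self.params[f"{name}.scale"] = g
        self.params[f"{name}.offset"] = b
        return g, b


def _check_channels(c_in, c_out, group):
    for c in (c_in, c_out):
        if c < group or c % group:
            raise ValueError(
                f"channel count {c} must be >= and divisible by group size {group}")


class _Block:
    """One encoder/decoder block (two 3x3x3 convs + norms, optional shortcut)."""

    def __init__(self, name, kind, c_in, c_out, cfg: NetworkConfig, store: _Store):
        _check_channels(c_in, c_out, cfg.norm_group_size)
        self.kind = kind
        self.slope = cfg.leaky_slope
        self.groups_in = c_in // cfg.norm_group_size
        self.groups_out = c_out // cfg.norm_group_size
        self.w1, self.b1 = store.conv(f"{name}.conv1", c_in, c_out, 3)
        self.w2, self.b2 = store.conv(f"{name}.conv2", c_out, c_out, 3)
        if kind == "preactivation":
            self.n1 = store.norm(f"{name}.norm1", c_in)
        else:
            self.n1 = store.norm(f"{name}.norm1", c_out)
        self.n2 = store.norm(f"{name}.norm2", c_out)
        self.shortcut = None
        if kind in ("residual", "preactivation") and c_in != c_out:
            self.shortcut = store.conv(f"{name}.shortcut", c_in, c_out, 1)

    def _short(self, x: Tensor) -> Tensor:
        if self.shortcut is None:
            return x
        return ag.conv3d(x, *self.shortcut, padding=0)

    def __call__(self, x: Tensor) -> Tensor:
        gs = lambda t, n, groups: ag.group_norm(t, *n, groups)
        if self.kind == "plain":
            h = ag.leaky_relu(gs(ag.conv3d(x, self.w1, self.b1), self.n1,
                                 self.groups_out), self.slope)
            return ag.leaky_relu(gs(ag.conv3d(h, self.w2, self.b2), self.n2,
                                    self.groups_out), self.slope)
        if self.kind == "residual":
            h = ag.leaky_relu(gs(ag.conv3d(x, self.w1, self.b1), self.n1,
                                 self.groups_out), self.slope)
            h = gs(ag.conv3d(h, self.w2, self.b2), self.n2, self.groups_out)
            return ag.leaky_relu(ag.add(h, self._short(x)), self.slope)
        # preactivation: norm -> activation -> conv, twice; identity-style sum
        h = ag.conv3d(ag.leaky_relu(gs(x, self.n1, self.groups_in), self.slope),
                      self.w1, self.b1)
        h = ag.conv3d(ag.leaky_relu(gs(h, self.n2, self.groups_out), self.slope),
                      self.w2, self.b2)
        return ag.add(h, self._short(x))


class UNet3D:
    """The shared U-shaped architecture; see module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        store = _Store(np.random.default_rng(seed), dtype)
        w = config.widths
        kind = config.block_kind
        self.stem = store.conv("stem", config.in_channels, w[0], 3)
        self.enc_blocks = [_Block(f"enc{i}", kind, w[i], w[i], config, store)
                           for i in range(config.n_levels)]
        self.down = [store.conv(f"down{i}", w[i], w[i + 1], 2)
                     for i in range(config.n_levels - 1)]
        self.up = [store.conv_t(f"up{i}", w[i + 1], w[i])
                   for i in range(config.n_levels - 1)]
        self.dec_blocks = [_Block(f"dec{i}", kind, 2 * w[i], w[i], config, store)
                           for i in range(config.n_levels - 1)]
        self.heads = [store.conv(f"head{i}", w[i], config.n_classes, 1)
                      for i in range(config.n_deep_supervision)]
        self._store = store

    # -- parameter access ---------------------------------------------------
    @property
    def parameters(self) -> dict[str, Parameter]:
        return self._store.params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters.values()))

    def zero_grad(self) -> None:
        for p in self.parameters.values():
            p.grad = None

    # -- forward ------------------------------------------------------------
    def forward(self, x, training: bool = False):
        """Run the network.

        ``x``: (B, in_channels, X, Y, Z) array or Tensor. Returns the list
        of logit Tensors [full, 1/2, 1/4, ...] in training mode, else the
        full-resolution logits only.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self._store.dtype))
        cfg = self.config
        stride = 2 ** (cfg.n_levels - 1)
        if any(s % stride for s in x.data.shape[2:]):
            raise ValueError(f"spatial dims {x.data.shape[2:]} must be "
                             f"divisible by {stride}")
        h = ag.conv3d(x, *self.stem)
        skips = []
        for i in range(cfg.n_levels):
            h = self.enc_blocks[i](h)
            if i < cfg.n_levels - 1:
                skips.append(h)
                h = ag.conv_down2(h, *self.down[i])
        outputs: list[Tensor] = []
        for i in range(cfg.n_levels - 2, -1, -1):
            h = ag.conv_up2(h, *self.up[i])
            h = self.dec_blocks[i](ag.concat([skips[i], h], axis=1))
            if i < cfg.n_deep_supervision:
                outputs.append(ag.conv3d(h, *self.heads[i], padding=0))
        outputs.reverse()  # index 0 = full resolution
        return outputs if training else outputs[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities (softmax over channel axis)."""
        logits = self.forward(x, training=False)
        return ag.softmax(logits, axis=1).data


def build_network(config: NetworkConfig, seed: int = 0,
                  dtype=np.float32) -> UNet3D:
    return UNet3D(config, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# closed-form parameter ledger
# ---------------------------------------------------------------------------

def _conv_p(ci, co, k):
    return ci * co * k ** 3 + co


def _norm_p(c):
    return 2 * c


def _block_p(kind, ci, co):
    convs = _conv_p(ci, co, 3) + _conv_p(co, co, 3)
    norms = _norm_p(ci if kind == "preactivation" else co) + _norm_p(co)
    shortcut = _conv_p(ci, co, 1) if (kind != "plain" and ci != co) else 0
    return convs + norms + shortcut


def parameter_ledger(config: NetworkConfig) -> dict[str, int]:
    """Per-layer closed-form trainable-scalar counts."""
    w = config.widths
    kind = config.block_kind
    ledger = {"stem": _conv_p(config.in_channels, w[0], 3)}
    for i in range(config.n_levels):
        ledger[f"enc{i}"] = _block_p(kind, w[i], w[i])
    for i in range(config.n_levels - 1):
        ledger[f"down{i}"] = _conv_p(w[i], w[i + 1], 2)
        ledger[f"up{i}"] = _conv_p(w[i + 1], w[i], 2)
        ledger[f"dec{i}"] = _block_p(kind, 2 * w[i], w[i])
    for i in range(config.n_deep_supervision):
        ledger[f"head{i}"] = _conv_p(w[i], config.n_classes, 1)
    return ledger


def count_parameters(config: NetworkConfig) -> int:
    """Total trainable scalars from the closed-form ledger."""
    return sum(parameter_ledger(config).values())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: UNet3D,
                    extra: dict | None = None) -> None:
    """Save weights + embedded config (+ optional JSON-serializable extras)."""
    payload = {f"param/{k}": p.data for k, p in model.parameters.items()}
    meta = {"config": asdict(model.config)}
    if extra:
        meta["extra"] = extra
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **payload)


def load_checkpoint(path: str | Path) -> tuple[UNet3D, dict]:
    path = str(path)
    with np.load(path if path.endswith(".npz") else path + ".npz",
                 allow_pickle=False) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        cfg_dict = meta["config"]
        cfg_dict["patch_size"] = tuple(cfg_dict["patch_size"])
        model = UNet3D(NetworkConfig(**cfg_dict))
        for k, p in model.parameters.items():
            p.data = archive[f"param/{k}"].copy()
    return model, meta.get("extra", {})
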