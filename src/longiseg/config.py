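"""YAML pipeline configuration: one file, sections mirroring the modules."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .augmentation import AugmentConfig
from .inference import InferenceConfig
from .losses import LossConfig
from .network import NetworkConfig
from .synthetic_data import PhantomSpec
from .training import TrainConfig

__all__ = ["SECTIONS", "load_config", "resolved_config", "dump_config"]

SECTIONS = {
    "phantom": PhantomSpec,
    "network": NetworkConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "augment": AugmentConfig,
    "inference": InferenceConfig,
}

_TUPLE_FIELDS = {"shape", "voxel_size", "lesion_radius_range", "patch_size",
                 "flip_p", "noise_sd_range", "smooth_sigma_range",
                 "intensity_scale_range", "intensity_shift_range",
                 "gamma_range", "lambdas", "target_voxel", "window"}


def _build(cls, values: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
               for k, v in values.items()}
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> dict:
    """Build all section configs from a YAML file (defaults where absent)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)
    return {name: _build(cls, raw.get(name, {}))
            for name, cls in SECTIONS.items()}


def resolved_config(configs: dict) -> dict:
    return {name: asdict(cfg) for name, cfg in configs.items()}


def dump_config(configs: dict, path: str | Path) -> None:
    """Write the fully-resolved configuration snapshot."""
    data = {name: {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in section.items()}
            for name, section in resolved_config(configs).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
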