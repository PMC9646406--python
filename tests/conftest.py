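import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from longiseg.augmentation import AugmentConfig
from longiseg.losses import LossConfig
from longiseg.network import NetworkConfig, build_network
from longiseg.synthetic_data import PhantomSpec, generate_case
from longiseg.training import TrainConfig, train

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

TINY_NET = dict(n_levels=3, base_width=8, n_deep_supervision=2,
                patch_size=(32, 32, 32))


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    return NetworkConfig(**TINY_NET)


@pytest.fixture(scope="session")
def lesion_case():
    """One default phantom case with new lesions (shared, read-only)."""
    return generate_case(PhantomSpec(), np.random.default_rng(42), "fixture")


@pytest.fixture(scope="session")
def overfit_run(tiny_config):
    """Desk-scale training run shared by learning/inference tests.

    Four lesion-bearing phantoms, 500 steps of the tiny configuration with
    class-averaged Dice + focal loss and augmentation off; plus one
    held-out lesion phantom and one held-out lesion-free phantom.
    """
    spec = PhantomSpec()
    rng = np.random.default_rng(123)
    train_cases = [generate_case(spec, rng, f"train_{i}") for i in range(4)]
    heldout = generate_case(spec, rng, "heldout")
    no_lesion = generate_case(
        dataclasses.replace(spec, n_new_lesions=0), rng, "nolesion")
    model = build_network(tiny_config, seed=0)
    result = train(
        model, train_cases,
        TrainConfig(steps=500, batch_size=2, lr=5e-3, seed=0),
        LossConfig(dice_mode="classwise", gt_downsample_mode="maxpool"),
        AugmentConfig(patch_size=tiny_config.patch_size, p_affine=0.0,
                      flip_p=(0.0, 0.0, 0.0), p_intensity=0.0))
    return {"model": model, "log": result.log, "train_cases": train_cases,
            "heldout": heldout, "no_lesion": no_lesion}
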