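"""Shared fixtures: small phantoms and session-scoped trained checkpoints.

Training fixtures are session-scoped because CPU training dominates suite
runtime; every test that needs a competent model shares the same checkpoint.
"""

import numpy as np
import pytest

from mslesionseg import (
    ElasticParams,
    PatchSamplingConfig,
    TrainConfig,
    UNetConfig,
    benchmark_config,
    build_training_patches,
    generate_study,
    znormalize,
)
from mslesionseg.segmenter import train


@pytest.fixture(scope="session")
def ms_config():
    return benchmark_config("ms_focal")


@pytest.fixture(scope="session")
def source_config():
    return benchmark_config("source_geographic")


@pytest.fixture(scope="session")
def ms_study(ms_config):
    return generate_study(ms_config, seed=7)


@pytest.fixture(scope="session")
def tiny_unet_cfg():
    return UNetConfig(n_levels=3, in_channels=1, base_features=4, out_classes=2, patch_size=16)


@pytest.fixture(scope="session")
def patch_cfg():
    return PatchSamplingConfig(16, 10, 10, 1)


def _training_patches(cfg, seeds, patch_cfg, elastic_seed=0):
    studies = []
    for s in seeds:
        st = generate_study(cfg, s)
        studies.append((znormalize(st.image), st.lesion_mask))
    return build_training_patches(studies, patch_cfg, ElasticParams(), elastic_seed)


@pytest.fixture(scope="session")
def ms_patches(ms_config, patch_cfg):
    # seeds chosen from phantoms known to admit lesion-free patch windows
    return _training_patches(ms_config, (0, 1, 2), patch_cfg)


@pytest.fixture(scope="session")
def source_patches(source_config, patch_cfg):
    return _training_patches(source_config, (100, 101, 102, 103, 104, 105), patch_cfg)


@pytest.fixture(scope="session")
def source_checkpoint(source_patches, tiny_unet_cfg):
    """Source-domain 'default' checkpoint (geographic lesions)."""
    return train(source_patches, TrainConfig(epochs=10, learning_rate=3e-3, batch_size=4, seed=5), tiny_unet_cfg)


@pytest.fixture(scope="session")
def ms_checkpoint(ms_patches, tiny_unet_cfg):
    """MS-domain model trained to desk-scale convergence."""
    return train(ms_patches, TrainConfig(epochs=45, learning_rate=1e-2, batch_size=4, seed=5), tiny_unet_cfg)
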