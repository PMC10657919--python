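"""Shared fixtures: small phantoms, datasets and models sized for unit tests."""

import numpy as np
import pytest

from wsunet.models import SCNNConfig, WSUnetConfig, build_scnn, build_wsunet
from wsunet.patches import PatchSamplingConfig, assemble_dataset
from wsunet.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(volume_shape=(24, 96, 96), lesion_radius_range_vox=(3, 5),
                         seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_phantom_config):
    return generate_cohort(small_phantom_config, 6)


@pytest.fixture(scope="session")
def small_sampling_config():
    return PatchSamplingConfig(patch_shape=(32, 32), n_tumour=6, n_contralateral=6,
                               offset_axial=5, offset_coronal=20, offset_sagittal=20,
                               seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, small_sampling_config):
    return assemble_dataset(small_cohort, small_sampling_config)


@pytest.fixture(scope="session")
def tiny_wsunet():
    """A 16x16 two-level WSUnet, dropout off, for fast exact checks."""
    cfg = WSUnetConfig(input_shape=(16, 16, 1), depth=2, base_filters=2,
                       spatial_dropout_rate=0.0)
    return build_wsunet(cfg, seed=5)


@pytest.fixture(scope="session")
def tiny_scnn():
    cfg = SCNNConfig(input_shape=(16, 16, 1), depth=2, base_filters=2,
                     spatial_dropout_rate=0.0, dense_width=8)
    return build_scnn(cfg, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
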