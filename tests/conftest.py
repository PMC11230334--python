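import numpy as np
import pytest

from trialmatch import HashedRandomProvider, SyntheticSpec, generate_coarse, generate_fine
from trialmatch.encoders import EncoderConfig


@pytest.fixture(scope="session")
def provider():
    return HashedRandomProvider(dimension=16, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort: 40 pairs, 30% eligible, 16-dim embeddings."""
    return SyntheticSpec(n_pairs=40, pos_fraction=0.3, embed_dim=16,
                         separation=0.9, seed=11)


@pytest.fixture(scope="session")
def coarse_pairs(small_spec):
    return generate_coarse(small_spec)


@pytest.fixture(scope="session")
def fine_pairs(small_spec):
    return generate_fine(small_spec)


@pytest.fixture
def mlp_config():
    return EncoderConfig("mlp", input_dim=16, projection_dim=8, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
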