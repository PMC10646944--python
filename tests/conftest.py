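import numpy as np
import pytest

from eqff.model import Model, ModelConfig
from eqff.presets import reduced_config


@pytest.fixture(scope="session")
def reduced_model():
    """Small untrained model with random weights (seeded)."""
    return Model(reduced_config(), seed=7)


@pytest.fixture(scope="session")
def midsize_model():
    """Model exercising the full (l_max = 2, multi-layer) path structure."""
    from eqff.allegro import AllegroConfig

    cfg = ModelConfig(
        allegro=AllegroConfig(
            n_scalar=32, n_channels=4, l_max=2, n_layers=2,
            two_body_hidden=(16, 32), latent_hidden=(32, 32), n_basis=6,
        ),
        head_hidden=(32, 16),
    )
    return Model(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
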