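"""Ready-made model configurations.

`full_config` is the full-size architecture (about 1.2 million trainable
parameters); `reduced_config` is the desk-scale variant used for training
experiments on synthetic data: one interaction layer, 32 scalar features,
l_max = 1 and correspondingly slimmer MLPs.
"""

from __future__ import annotations

from .allegro import AllegroConfig
from .model import ModelConfig


def full_config(**overrides) -> ModelConfig:
    return ModelConfig(allegro=AllegroConfig(), **overrides)


def reduced_config(**overrides) -> ModelConfig:
    allegro = AllegroConfig(
        n_scalar=32,
        n_channels=4,
        l_max=1,
        n_layers=1,
        two_body_hidden=(32, 32),
        latent_hidden=(64,),
        n_basis=8,
    )
    overrides.setdefault("head_hidden", (64, 32))
    return ModelConfig(allegro=allegro, **overrides)
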