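"""Shared fixtures: small phantoms and a briefly-trained micro network.

Fixtures are generated programmatically; nothing is read from disk.  The
micro network (base 4 channels, 32-pixel sections, depth 3) is trained for
a handful of steps only — enough for smoke-level inference tests, not for
accuracy claims, which live in the acceptance tests at the tiny
(base 8 / side 64) scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from sbfseg.model import NetworkConfig, TrainConfig, build_network, stack_pairs, train
from sbfseg.preprocess import augment_training_set, normalize
from sbfseg.synthetic import PhantomSpec, generate_phantom

MICRO_NET = NetworkConfig(input_side=32, base_channels=4, depth=3)


def small_spec(stage: int = 2, seed: int = 0, cube_side: int = 32) -> PhantomSpec:
    from sbfseg.synthetic import fractions_for_cube

    return PhantomSpec(stage=stage, cube_side=cube_side, seed=seed,
                       organelle_fractions=fractions_for_cube(cube_side))


@pytest.fixture(scope="session")
def small_phantom():
    """A stage-2 phantom in a 32-cube: (RawVolume, LabelVolume)."""
    return generate_phantom(small_spec(stage=2, seed=11))


@pytest.fixture(scope="session")
def phantom_pairs():
    """Three normalized phantom/label pairs (stages 1, 3, 5) in 32-cubes."""
    pairs = []
    for stage, seed in ((1, 3), (3, 5), (5, 7)):
        raw, lab = generate_phantom(small_spec(stage=stage, seed=seed))
        pairs.append((normalize(raw), lab))
    return pairs


@pytest.fixture(scope="session")
def micro_net(phantom_pairs):
    """A micro attention U-Net trained briefly on two phantoms."""
    net = build_network(MICRO_NET, seed=0)
    X, Y = stack_pairs(augment_training_set(phantom_pairs[:2]))
    cfg = TrainConfig(base_lr=1e-3, epochs=2, batch_size=8,
                      sections_per_epoch=96, seed=0)
    net, _history = train(net, (X, Y), None, cfg)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
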