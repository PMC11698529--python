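import numpy as np
import pytest

from multiplexcoop import pair_engine as pe
from multiplexcoop.games import GameSpec
from multiplexcoop.multiplex import MultiplexNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net():
    """4-node, 2-layer example: layer1 {01, 12}, layer2 {01, 23}; O = 1/3."""
    return MultiplexNetwork([[(0, 1), (1, 2)], [(0, 1), (2, 3)]], 4)


@pytest.fixture
def donation_games():
    return GameSpec.donation((5.0, 3.0), (1.0, 1.0))


@pytest.fixture
def toy_strategies():
    return {
        "allc_linked": pe.LinkedStrategy.allc(),
        "alld_linked": pe.LinkedStrategy.alld(),
        "allc_unlinked": pe.UnlinkedStrategy.allc(),
        "alld_unlinked": pe.UnlinkedStrategy.alld(),
        "tft_unlinked": pe.UnlinkedStrategy.tft(),
        "resident": pe.LinkedStrategy.from_tuple((1, 1, 0, 0, 1, 1, 1, 0, 0, 1)),
        "single_layer_defector": pe.LinkedStrategy.from_tuple(
            (0, 0, 0, 0, 0, 1, 1, 0, 0, 1)),
    }


def random_linked(rng):
    return pe.LinkedStrategy(p0=rng.random(2), cond=rng.random((2, 4)))


def random_unlinked(rng):
    return pe.UnlinkedStrategy(p0=rng.random(2), pC=rng.random(2), pD=rng.random(2))
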