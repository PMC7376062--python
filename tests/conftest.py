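import numpy as np
import pytest

from follisim.network import CD21NEG_RC, FDC, ReticularNetwork, StromalNode


def make_network(positions, edges, subtypes=None, rates=None):
    return ReticularNetwork.from_arrays(
        np.asarray(positions, float), edges, subtypes=subtypes,
        secretion_rates=rates,
    )


@pytest.fixture
def triangle_net():
    return make_network(
        [[0, 0, 0], [10, 0, 0], [5, 8, 0]], [(0, 1), (1, 2), (0, 2)]
    )


@pytest.fixture
def path_net():
    """3-node path A-B-C."""
    return make_network([[0, 0, 0], [10, 0, 0], [20, 0, 0]], [(0, 1), (1, 2)])


@pytest.fixture
def star_net():
    """4-node star: hub 0 with three leaves."""
    return make_network(
        [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]],
        [(0, 1), (0, 2), (0, 3)],
    )


@pytest.fixture
def mixed_subtype_net():
    """6 nodes with an FDC hub; FDC mean degree > RC mean degree."""
    pos = [[0, 0, 0], [10, 0, 0], [0, 10, 0], [20, 0, 0], [20, 10, 0], [30, 0, 0]]
    edges = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (3, 5)]
    subtypes = [FDC, FDC, CD21NEG_RC, CD21NEG_RC, CD21NEG_RC, CD21NEG_RC]
    return make_network(pos, edges, subtypes=subtypes)


@pytest.fixture
def small_follicle():
    from follisim.synthesis import SynthesisParams, synthesize_follicle_network

    return synthesize_follicle_network(
        SynthesisParams(n_fdc=27, n_rc=33, follicle_radius=75.0, seed=42)
    )
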