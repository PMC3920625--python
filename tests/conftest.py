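import itertools

import numpy as np
import pytest

from cspbn import apoptosis_network, wnt5a_network


@pytest.fixture
def apoptosis():
    return apoptosis_network(0.5)


@pytest.fixture
def wnt5a_verif():
    """WNT5A network as set up for the reachability study."""
    return wnt5a_network(0.5, 0.5, 0.3)


@pytest.fixture
def wnt5a_control():
    """WNT5A network as set up for the optimal-control study."""
    return wnt5a_network(0.8, 0.2, 0.3, x0=(1, 1, 0, 1, 0, 0))


def all_binary_points(names):
    """Every binary assignment over the given variable names."""
    names = sorted(names)
    for bits in itertools.product((0, 1), repeat=len(names)):
        yield dict(zip(names, bits))
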