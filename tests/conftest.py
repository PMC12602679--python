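import numpy as np
import pytest

from scrnlevels import fixtures as fx


@pytest.fixture
def cascade_net():
    return fx.cascade(alpha=1.0, beta=1.0, n_tot=2)


@pytest.fixture
def histone_net():
    return fx.histone(d_tot=2)


@pytest.fixture
def full_chromatin_net():
    return fx.full_chromatin(d_tot=2)


@pytest.fixture
def biparallel_net():
    return fx.biparallel(s_tot=2)


@pytest.fixture
def two_component_net():
    return fx.two_component(n1=2, n2=2)


@pytest.fixture
def coupled_net():
    return fx.coupled(n1=2, n2=2, n3=1)


def coefficients_set(functions):
    """Canonical coefficient tuples of a list of level functions."""
    return {tuple(int(c) for c in f.canonical().coefficients) for f in functions}


def pick_function(functions, coeffs):
    """The enumerated level function with the given coefficient tuple."""
    for f in functions:
        if tuple(int(c) for c in f.coefficients) == tuple(coeffs):
            return f
    raise AssertionError(f"no level function with coefficients {coeffs}")
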