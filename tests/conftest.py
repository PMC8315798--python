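"""Shared fixtures: small synthetic models reused across the suite."""

import numpy as np
import pytest

from neurogain import (
    GainModulation,
    ModelParameters,
    SyntheticSpec,
    make_connectome,
    make_expression_map,
)
from neurogain.dynamics import apply_fic, solve_fixed_point


@pytest.fixture(scope="session")
def spec10():
    return SyntheticSpec(n_nodes=10, seed=1)


@pytest.fixture(scope="session")
def sc10(spec10):
    return make_connectome(spec10)


@pytest.fixture(scope="session")
def spec30():
    return SyntheticSpec(n_nodes=30, seed=0)


@pytest.fixture(scope="session")
def sc30(spec30):
    return make_connectome(spec30)


@pytest.fixture(scope="session")
def h30(spec30, sc30):
    return make_expression_map(spec30, sc30.D, seed=10)


@pytest.fixture(scope="session")
def params():
    return ModelParameters(G=0.5, sigma=0.01)


@pytest.fixture(scope="session")
def fic10(sc10, params):
    return apply_fic(sc10, params)


@pytest.fixture(scope="session")
def steady10(sc10, params, fic10):
    return solve_fixed_point(sc10, params, w_EI=fic10)


@pytest.fixture(scope="session")
def fic30(sc30, params):
    return apply_fic(sc30, params)


@pytest.fixture(scope="session")
def steady30(sc30, params, fic30):
    return solve_fixed_point(sc30, params, w_EI=fic30)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
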