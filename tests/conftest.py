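import numpy as np
import pytest

from saxskit import (
    FormFactorTable, SolventModel, ToySpec, make_toy, default_q_grid,
)


@pytest.fixture(scope="session")
def q_saxs():
    """q-grid over the well-validated form-factor range."""
    return np.linspace(0.0, 0.33, 34)


@pytest.fixture(scope="session")
def q_wide():
    return default_q_grid(0.5, 51)


@pytest.fixture(scope="session")
def coil30():
    return make_toy(ToySpec("random_coil", 30, 3.8, "C", seed=1))


@pytest.fixture(scope="session")
def coil100():
    return make_toy(ToySpec("random_coil", 100, 3.8, "C", seed=0))


@pytest.fixture(scope="session")
def ring100():
    return make_toy(ToySpec("ring", 100, 20.0, "C", seed=0))


@pytest.fixture
def pair5():
    return make_toy(ToySpec("pair", 2, 5.0, "C", seed=0))


def table_for(structure, q, **kw):
    return FormFactorTable.from_structure(structure, np.asarray(q, float), **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
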