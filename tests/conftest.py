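import numpy as np
import pytest
from hypothesis import settings

from oecpkit import (
    PermittivitySpectrum,
    crown_truth,
    default_bare_contact,
    default_contact,
    default_grid,
    media_catalogue,
    root_truth,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def crown(grid):
    return crown_truth(grid)


@pytest.fixture(scope="session")
def root(grid):
    return root_truth(grid)


@pytest.fixture(scope="session")
def catalogue():
    return media_catalogue()


@pytest.fixture
def contact():
    return default_contact(seed=7)


@pytest.fixture
def bare_contact():
    return default_bare_contact(seed=7)


def constant_spectrum(grid, value, label=""):
    return PermittivitySpectrum(
        grid=grid, eps_real=np.full(grid.n_points, float(value)), label=label
    )


@pytest.fixture(scope="session")
def make_constant(grid):
    def _make(value, label=""):
        return constant_spectrum(grid, value, label)

    return _make
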