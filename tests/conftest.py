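import numpy as np
import pandas as pd
import pytest

from hoxpos import (
    make_reference,
    simulate_cells,
    simulate_homeo_population,
)
from hoxpos.synthetic import DEFAULT_HOX_SPECS


@pytest.fixture(scope="session")
def default_reference():
    return make_reference(DEFAULT_HOX_SPECS, 201)


@pytest.fixture(scope="session")
def mapping_sim(default_reference):
    """Default mapping simulation: 500 cells, r=20, λ=0.1."""
    m, truth = simulate_cells(
        default_reference, 500, r=20.0, lambda_bg=0.1, seed=11
    )
    return m, truth, default_reference


@pytest.fixture(scope="session")
def homeo_sim():
    """Six planted homeodomain-code clusters with linked Ig programs."""
    m, truth = simulate_homeo_population(
        6, cells_per_cluster=40, link_strength=4.0, seed=21, n_flat=100
    )
    return m, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


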