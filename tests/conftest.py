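"""Shared fixtures: small synthetic experiments generated at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recipro.simulate import SimulationConfig, simulate_dataset
from recipro.traits import add_derived_traits


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down experiment: 4 pops x 6 lines, 60 markers."""
    return SimulationConfig(n_lines_per_pop=6, n_markers=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, truth = simulate_dataset(small_config)
    return ds, truth


@pytest.fixture(scope="session")
def derived_pheno(small_dataset) -> pd.DataFrame:
    ds, _ = small_dataset
    return add_derived_traits(ds.phenotypes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
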