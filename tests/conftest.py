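import dataclasses

import numpy as np
import pytest

from mrbma import PriorConfig, harmonize, scenario_library, simulate


@pytest.fixture(scope="session")
def library():
    return scenario_library()


@pytest.fixture(scope="session")
def single_causal_dataset(library):
    """One harmonized draw of the single-causal scenario, shared across tests."""
    exposure, outcome, truth = simulate(library["single-causal"])
    return harmonize(exposure, outcome), truth


@pytest.fixture(scope="session")
def null_dataset(library):
    exposure, outcome, truth = simulate(library["null"])
    return harmonize(exposure, outcome), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_prior():
    return PriorConfig(max_model_size=2)


def replace_seed(scenario, seed):
    return dataclasses.replace(scenario, seed=seed)
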