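import numpy as np
import pytest

from glycoclust.pipeline import quantify_specimen
from glycoclust.synthetic import SimulationParams, simulate_specimen


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=3)


@pytest.fixture(scope="session")
def specimen_all_types(default_params):
    """One rendered specimen seeded with all three cluster types."""
    return simulate_specimen(default_params, index=0, profile="AB_dual")


@pytest.fixture(scope="session")
def quantified(specimen_all_types):
    quant, maps = quantify_specimen(specimen_all_types.specimen_id, specimen_all_types.channels)
    return quant, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
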