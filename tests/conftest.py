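import numpy as np
import pytest

from irinosim.fixtures import default_fixture_tables, make_reference_profile
from irinosim.model import IrinotecanPBPK
from irinosim.population import PopulationModel


@pytest.fixture(scope="session")
def tables():
    return default_fixture_tables()


@pytest.fixture(scope="session")
def base_params(tables):
    return tables.base_params


@pytest.fixture(scope="session")
def base_exposures(base_params):
    return IrinotecanPBPK(base_params).exposures()


@pytest.fixture(scope="session")
def base_simulation(base_params):
    return IrinotecanPBPK(base_params).simulate(t_end=100.0)


@pytest.fixture(scope="session")
def population_model(tables):
    return PopulationModel(
        tables.base_params, tables.dists, tables.genetics, tables.binding,
        tables.renal,
    )


@pytest.fixture(scope="session")
def noiseless_reference(base_params):
    return make_reference_profile(base_params, noise_cv=0.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
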