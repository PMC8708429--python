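import importlib.resources

import pytest

from phytotraits import pipeline, synthetic_data
from phytotraits.trait_table import load_trait_table

FIXTURE_TABLE = importlib.resources.files("phytotraits") / "data/trait_table_fixture.csv"


@pytest.fixture(scope="session")
def fixture_table():
    return load_trait_table(str(FIXTURE_TABLE))


@pytest.fixture(scope="session")
def small_config():
    """A fast survey: same structure, fewer samples and taxa."""
    return synthetic_data.SimulationConfig(
        seed=11, n_samples=176, taxon_pool=25, wb_per_area=11, stations_per_wb=2
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthetic_data.simulate_survey(small_config)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return pipeline.prepare_bundle(small_bundle)
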