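import numpy as np
import pytest

from ichno.catalogue import load_catalogue, load_water_rule, load_weight_profiles
from ichno.grids import GridSpec
from ichno.synthetic_crater import worked_fixture


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def profiles_eq():
    return load_weight_profiles(source="equations")


@pytest.fixture(scope="session")
def profiles_t5():
    return load_weight_profiles(source="table5")


@pytest.fixture(scope="session")
def water_rule():
    return load_water_rule()


@pytest.fixture(scope="session")
def fixture_landscape():
    return worked_fixture()


@pytest.fixture
def small_grid():
    return GridSpec(
        origin_x=0.0, origin_y=200.0, cell_size=10.0, n_rows=20, n_cols=20,
        crs_token="SYNTH:LOCAL",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
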