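import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import box

from flywaylinks.simulate import SimulationParams, simulate
from flywaylinks.types import Country, CountryLayer, StudyRegion

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_strip_layer():
    """Toy layer: 2 European squares up north, 4 collinear African unit
    squares (B, D, C, X from west to east) on one latitude band."""
    countries = [
        Country("EA0", "Euroland A", "Europe", "western Europe", box(0, 50, 2, 52)),
        Country("EB0", "Euroland B", "Europe", "eastern Europe", box(2, 50, 4, 52)),
        Country("AB0", "Afriland B", "Africa", "western Africa", box(0, 0, 1, 1)),
        Country("AD0", "Afriland D", "Africa", "western Africa", box(1, 0, 2, 1)),
        Country("AC0", "Afriland C", "Africa", "eastern Africa", box(2, 0, 3, 1)),
        Country("AX0", "Afriland X", "Africa", "eastern Africa", box(3, 0, 4, 1)),
    ]
    return CountryLayer(countries)


@pytest.fixture
def strip_layer():
    return make_strip_layer()


@pytest.fixture
def strip_region(strip_layer):
    return StudyRegion({c.code: (c.continent, c.subregion) for c in strip_layer})


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_countries_europe=6,
        n_countries_africa=8,
        n_landbirds=4,
        n_raptors=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_params):
    return simulate(small_params)


@pytest.fixture(scope="session")
def default_world():
    return simulate(SimulationParams(seed=5))


def cea_point(lon, lat, R=6_371_007.180918475):
    """Independent cylindrical equal-area projection used by test oracles."""
    return R * np.radians(lon), R * np.sin(np.radians(lat))
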