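from hypothesis import HealthCheck, settings
import pytest

from dietexpose.fixtures import reference_aggregates
from dietexpose.records import ConcentrationRecord, default_config

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def ref():
    return reference_aggregates()


def make_conc(sample_id="s", year=2015, food="flour_products", value=50.0,
              lod=10.0, detected=True):
    return ConcentrationRecord(
        sample_id=sample_id,
        year=year,
        food_type=food,
        value_mg_per_kg=value if detected else None,
        lod_mg_per_kg=lod,
        detected=detected,
    )


@pytest.fixture
def conc_factory():
    return make_conc
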