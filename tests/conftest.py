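import pytest

from bmicorrect import AnthropometricRecord, published_models
from bmicorrect.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_growth_fixture,
)


@pytest.fixture(scope="session")
def growth_table():
    return generate_growth_fixture(7)


@pytest.fixture(scope="session")
def models():
    return published_models()


@pytest.fixture(scope="session")
def small_cohort(growth_table):
    return generate_cohort(SimulationConfig(n=400, seed=3, fixture_seed=7),
                           growth_table)


def make_record(**overrides):
    """A fully specified adult-age record at convenient defaults."""
    base = dict(
        id="r1",
        sex="male",
        age_months=252.0,
        sr_height_cm=175.0,
        sr_weight_kg=70.0,
        measured_height_cm=174.0,
        measured_weight_kg=71.0,
        puberty=3,
        body_size_estimation="AboutRight",
        dieting=False,
        cesd=10.0,
        self_rated_health=4.0,
        self_esteem=4.0,
        race_ethnicity="White",
        parent_education="College_plus",
        sample_weight=1.0,
    )
    base.update(overrides)
    return AnthropometricRecord(**base)


@pytest.fixture
def record():
    return make_record()
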