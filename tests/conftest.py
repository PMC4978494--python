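import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hercua import CohortCUA, generate_inputs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def inputs():
    """Calibrated synthetic inputs (default NZ-like configuration)."""
    return generate_inputs()


@pytest.fixture(scope="session")
def model(inputs):
    return CohortCUA.from_inputs(inputs)


@pytest.fixture(scope="session")
def fitted(model):
    """Deterministic base case over the full age-group grid."""
    return model.fit()


def flat_life_table(rate: float):
    from hercua import LifeTable

    ages = np.arange(25, 111)
    return LifeTable(ages, np.full(ages.size, rate))


def flat_emr(rate: float, cure_year: int = 20):
    from hercua import EmrCurve

    return EmrCurve(np.full(cure_year, rate), cure_year)
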