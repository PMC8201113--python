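import pytest
from hypothesis import HealthCheck, settings

import kanoqual as kq

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def instrument():
    return kq.default_instrument()


@pytest.fixture(scope="session")
def survey_table():
    return kq.hospital_survey_table()


@pytest.fixture(scope="session")
def survey_results(survey_table):
    return kq.analyze(survey_table)


@pytest.fixture
def mini_instrument():
    attrs = tuple(kq.Attribute(i, f"attribute {i}", "efficiency")
                  for i in (1, 2, 3, 4))
    return kq.Instrument(attrs, name="mini")
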