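import pytest
from hypothesis import HealthCheck, settings

from tracerisk import core

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    return core.load_defaults()


@pytest.fixture(scope="session")
def specs(defaults):
    return defaults[0]


@pytest.fixture(scope="session")
def spec_by_symbol(specs):
    return core.element_table(specs)


@pytest.fixture(scope="session")
def scenarios(defaults):
    return defaults[1]


@pytest.fixture(scope="session")
def adult(scenarios):
    return next(s for s in scenarios if s.label == "adult")


@pytest.fixture(scope="session")
def child(scenarios):
    return next(s for s in scenarios if s.label == "child")


@pytest.fixture(scope="session")
def survey():
    return core.load_market_survey()


@pytest.fixture(scope="session")
def survey_by_cell(survey):
    return {(r.market, r.body_part, r.element): r for r in survey}
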