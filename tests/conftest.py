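import pytest
from hypothesis import HealthCheck, settings

from scedkit import PipelineConfig, analyze_study
from scedkit.synthetic_data import generate_design, generate_series, named_scenario

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def plans():
    return generate_design()


@pytest.fixture(scope="session")
def rmt_series(plans):
    return generate_series(named_scenario("rmt_effect"), plans, seed=1)


@pytest.fixture(scope="session")
def rmt_report(rmt_series):
    return analyze_study(rmt_series, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def clinical_series(plans):
    return generate_series(named_scenario("clinical_clean"), plans, seed=1)


@pytest.fixture(scope="session")
def null_series(plans):
    return generate_series(named_scenario("cmct_null_highvar"), plans, seed=1)
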