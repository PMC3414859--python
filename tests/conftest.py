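import pytest
from hypothesis import HealthCheck, settings

from picosearch import PicoQuestion, load_table1_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mucolytics_question() -> PicoQuestion:
    """The worked example: mucolytics for chronic bronchitis / COPD."""
    return PicoQuestion(
        question_id="mucolytics",
        population_terms=("chronic bronchitis", "COPD"),
        intervention_terms=("mucolytics",),
        comparison_terms=("placebo",),
        outcome_terms=("exacerbations",),
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()
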