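import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from needsalloc import AssetIndex, SurveyDesign, generate_survey, load_published_table
from needsalloc.pipeline import fixture_district_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    return load_published_table("table3")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_published_table("table2")


@pytest.fixture(scope="session")
def fixture_table() -> pd.DataFrame:
    """Published district table with implied stunting and recomputed shares."""
    return fixture_district_table()


@pytest.fixture(scope="session")
def default_survey():
    """One full-scale synthetic survey (26 districts x 1,200 households)."""
    return generate_survey(SurveyDesign(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_survey):
    survey, truth = default_survey
    model = AssetIndex().fit(survey)
    return survey, truth, model
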