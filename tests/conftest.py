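import pytest

from lusmorph import build_training_fixture, build_validation_fixture
from lusmorph.synthetic_data import cohort_to_dataframe, default_config, generate_cohort


@pytest.fixture(scope="session")
def training_fixture():
    return build_training_fixture()


@pytest.fixture(scope="session")
def validation_fixture():
    return build_validation_fixture()


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Default calibrated synthetic cohort, n = 2000, seed 0 (exam level)."""
    return cohort_to_dataframe(generate_cohort(default_config()))
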