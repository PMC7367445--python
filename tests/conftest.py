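import pytest

from afscreen.accuracy import DichotomyPolicy
from afscreen.study import reference_study_cohort


@pytest.fixture(scope="session")
def study_df():
    """The deterministic 604-row reference screening cohort."""
    return reference_study_cohort()


@pytest.fixture(scope="session")
def default_policy():
    return DichotomyPolicy()


@pytest.fixture(scope="session")
def published_policy():
    return DichotomyPolicy.published_tables()
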