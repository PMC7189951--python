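import os
import sys

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny8():
    from birthspacing.simulate import make_fixture

    return make_fixture("tiny8")


@pytest.fixture(scope="session")
def paper_like_cohort():
    from birthspacing.simulate import make_fixture

    return make_fixture("paper_like_812")
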