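import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wt_ns1738():
    from coagonist import GroupSummary

    return GroupSummary("a1b2g2L", "NS-1738", -0.70, 0.23, 25)


@pytest.fixture
def wt_pam2():
    from coagonist import GroupSummary

    return GroupSummary("a1b2g2L", "PAM-2", -0.39, 0.10, 25)
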