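import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aclrisk import orientation, synth
from aclrisk.features import FEATURE_NAMES

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def static_trial():
    return synth.synthesize_static_trial(duration=2.0, seed=42)


@pytest.fixture(scope="session")
def static_correction(static_trial):
    return orientation.estimate_static_alignment(static_trial)


@pytest.fixture(scope="session")
def nr_means():
    return dict(zip(FEATURE_NAMES, synth._NR_MEAN))


@pytest.fixture(scope="session")
def r_means():
    return dict(zip(FEATURE_NAMES, synth._R_MEAN))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
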