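import warnings

import pytest
from hypothesis import settings, HealthCheck

warnings.filterwarnings("ignore", category=RuntimeWarning)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reg():
    from scfsolub import reg_dataset
    return reg_dataset()


@pytest.fixture(scope="session")
def fast_config():
    from scfsolub import FitConfig
    return FitConfig(objective="aard", n_starts=4, seed=1)
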