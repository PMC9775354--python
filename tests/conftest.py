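import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20181126)


@pytest.fixture
def noise_free_scenario():
    from bryoflux.synthetic import default_scenario

    return default_scenario(seed=7).noise_free()
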