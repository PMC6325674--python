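import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tox_ds_small():
    """Separable 64-bit toxicity fixture, 100 per class."""
    from toxsa.synth_fixtures import ToxGenConfig, gen_tox_data

    return gen_tox_data(ToxGenConfig(
        n_per_class=100, n_bits=64, n_informative_bits=4,
        flip_noise=0.05, seed=11,
    ))


@pytest.fixture
def sa_ds_small():
    """64-bit synthetic-accessibility fixture, n=300."""
    from toxsa.synth_fixtures import SaGenConfig, gen_sascore_data

    return gen_sascore_data(SaGenConfig(n=300, n_bits=64, noise_sd=0.3, seed=11))
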