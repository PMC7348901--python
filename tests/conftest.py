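import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 5-channel mixture (3 abdominal + 2 thoracic), fmSNR -10 dB."""
    from nsfecg.synth import simulate_record

    return simulate_record(
        n_abdominal=3, n_thoracic=2, channel_snr_db=None, seed=11
    )


@pytest.fixture(scope="session")
def noisy_record():
    """Benchmark-condition mixture: channel SNR 12 dB, fmSNR -10 dB."""
    from nsfecg.synth import simulate_record

    return simulate_record(n_abdominal=3, n_thoracic=2, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
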