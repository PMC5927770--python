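import numpy as np
import pytest

from quantalysis import RecordingConfig, ReleaseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wt_release():
    return ReleaseModel(n_sites=150, p_max=0.85, ca_half=1.7, hill=2.2,
                        q_mean=0.6, q_cv=0.3)


@pytest.fixture
def quiet_config():
    """Noise-free current-clamp recording for exact-value tests."""
    return RecordingConfig(sampling_rate=10_000.0, duration=2.0,
                           noise_sd=0.0, mini_rate=0.0)
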