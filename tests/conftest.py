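import numpy as np
import pytest

from rcspe.synthetic import SimConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Cheap paired session: 10 trials/class, strong signal."""
    cfg = SimConfig(
        n_trials_per_class=10, snr_eeg=10.0, snr_fnirs=5.0, seed=7,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """One session under the default study conditions."""
    return generate_session(SimConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, scale=1.0):
    """Random symmetric positive-definite matrix."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
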