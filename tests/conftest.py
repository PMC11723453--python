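import numpy as np
import pytest

from rowkinetics import synthetic
from rowkinetics.model import dataset_from_sessions


def clean_params(params):
    """Copy TechniqueParams with measurement noise disabled."""
    d = dict(params.__dict__)
    d["noise_sd"] = 0.0
    return synthetic.TechniqueParams(**d)


@pytest.fixture(scope="session")
def ergo_session_clean():
    """One noise-free ergometer session: 10 cycles at 50 Hz."""
    profile, params = synthetic.sample_subject("ergometer", 42, noise_sd=0.0)
    return synthetic.simulate_ergo_session(profile, params, 10, sample_rate_hz=50.0)


@pytest.fixture(scope="session")
def boat_session_clean():
    """One noise-free boat session long enough for the 0.1 Hz high-pass."""
    profile, params = synthetic.sample_subject("boat", 7, noise_sd=0.0)
    return synthetic.simulate_boat_session(profile, params, 25, sample_rate_hz=100.0)


@pytest.fixture(scope="session")
def ergo_sessions_noisy():
    """Three noisy ergometer subjects x 12 cycles (default study noise)."""
    sessions = []
    for i in range(3):
        profile, params = synthetic.sample_subject("ergometer", 100 + i)
        sessions.append(
            synthetic.simulate_ergo_session(profile, params, 12, sample_rate_hz=50.0)
        )
    return sessions


@pytest.fixture(scope="session")
def boat_session_noisy():
    profile, params = synthetic.sample_subject("boat", 11)
    return synthetic.simulate_boat_session(profile, params, 25, sample_rate_hz=100.0)


@pytest.fixture(scope="session")
def small_dataset(ergo_sessions_noisy):
    """CycleDataset over the three noisy ergometer sessions (33 cycles)."""
    return dataset_from_sessions(ergo_sessions_noisy)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
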