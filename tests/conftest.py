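import numpy as np
import pytest

from saccerp.simulate import SessionParams, default_kernels, generate_session

POSTERIOR_8 = ("PO7", "PO8", "O1", "O2", "P7", "P8", "Pz", "Cz")


@pytest.fixture(scope="session")
def clean_session():
    """Short noiseless, head-fixed, drift-free session with 8 channels."""
    params = SessionParams(
        duration=120.0, seed=11, head_motion_amp=0.0, drift_rate=0.0,
        noise_scale=0.0, n_channels=len(POSTERIOR_8),
    )
    kernels = default_kernels(params.eeg_rate, labels=POSTERIOR_8)
    return generate_session(params, kernels=kernels)


@pytest.fixture(scope="session")
def moving_session():
    """Short session with head motion, default jitter and EEG noise."""
    params = SessionParams(
        duration=120.0, seed=12, head_motion_amp=1.0, drift_rate=0.0,
        n_channels=len(POSTERIOR_8),
    )
    kernels = default_kernels(params.eeg_rate, labels=POSTERIOR_8)
    return generate_session(params, kernels=kernels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
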