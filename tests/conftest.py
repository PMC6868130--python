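import numpy as np
import pytest

from dlmss import trajsim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_state():
    """The reference three-state switching model."""
    return trajsim.three_state_model()


@pytest.fixture(scope="session")
def fbm_params():
    return trajsim.FbmParams()


def brownian_track(D, n_frames, rng, tau=0.032):
    steps = trajsim.simulate_brownian_steps(D, tau, n_frames - 1, rng)
    return np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])


def fbm_track(H, eta, n_frames, rng, fbm=None, step_unit=1.0):
    fbm = fbm or trajsim.FbmParams()
    steps = trajsim.simulate_fbm_steps(H, fbm, eta, n_frames - 1, rng, step_unit=step_unit)
    return np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
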