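import numpy as np
import pytest

from lccm.circuits import SourceWaveform, build_lccm, observe, simulate
from lccm.inversion import make_predictor
from lccm.priors import active_priors, default_lccm_priors
from lccm.stimulus import make_tone_train


@pytest.fixture(scope="session")
def lccm_model():
    return build_lccm()


@pytest.fixture(scope="session")
def five_tone_train():
    return make_tone_train(5, 0.5)


@pytest.fixture(scope="session")
def five_tone_traj(lccm_model, five_tone_train):
    """One prior-parameterized 5-tone trial, shared across tests."""
    return simulate(lccm_model, five_tone_train, t_span=(-0.1, 2.5))


@pytest.fixture(scope="session")
def five_tone_waveform(five_tone_traj, lccm_model):
    return observe(five_tone_traj, lccm_model, fs_out=1000.0)


@pytest.fixture(scope="session")
def noise_free_data(lccm_model, five_tone_train):
    """Noise-free 125 Hz dataset generated at the prior expectations."""
    priors = default_lccm_priors(lccm_model)
    predict = make_predictor(lccm_model, five_tone_train, priors)
    theta0 = np.zeros(len(active_priors(priors)))
    y = predict(theta0)
    t = -0.1 + np.arange(y.size) / 125.0
    return SourceWaveform(t=t, y=y, fs=125.0, normalized=True), priors, predict
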