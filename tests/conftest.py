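import numpy as np
import pytest

from pigvoc.audio import AudioSignal
from pigvoc.gmm_hmm import ClassHMM


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_44k():
    """1 s, 440 Hz sine at 44.1 kHz, amplitude 0.8."""
    sr = 44_100
    t = np.arange(sr) / sr
    return AudioSignal(0.8 * np.sin(2 * np.pi * 440.0 * t), sr)


def make_tiny_hmm(n_states=3, dim=1, means=None, self_loop=0.6):
    """Small left-to-right HMM with K=1 unit-variance emissions."""
    pi = np.zeros(n_states)
    pi[0] = 1.0
    trans = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        trans[i, i] = self_loop
        trans[i, i + 1] = 1.0 - self_loop
    trans[-1, -1] = 1.0
    if means is None:
        means = np.arange(n_states, dtype=float)[:, None, None] * 3.0
        means = np.tile(means, (1, 1, dim))
    weights = np.ones((n_states, 1))
    variances = np.ones((n_states, 1, dim))
    return ClassHMM(pi, trans, weights, np.asarray(means, float), variances)


@pytest.fixture
def tiny_hmm():
    return make_tiny_hmm()
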