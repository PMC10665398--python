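import numpy as np
import pytest

from stiffwave import SessionConfig, WaveformConfig, gen_beat_waveform, gen_session


@pytest.fixture
def noise_free_waveform():
    """Six noise-free beats at 100 Hz / 60 bpm with K=2, B=0.5."""
    return gen_beat_waveform(
        WaveformConfig(n_beats=6, k_true=2.0, b_true=0.5, seed=0))


@pytest.fixture
def fig1_session():
    """Session reproducing the worked detection example: true threshold
    50 mA with an isolated artifact spike after the 20 mA stimulus."""
    return gen_session(SessionConfig(threshold_ma=50, spike_at_ma=20, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
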