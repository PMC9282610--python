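import numpy as np
import pytest

from phrasal import synth, tfr


@pytest.fixture(scope="session")
def small_bank():
    """20-wavelet bank spanning the same 1-50 Hz / 3-30 cycle ranges."""
    return tfr.WaveletBank(np.geomspace(1.0, 50.0, 20), np.geomspace(3.0, 30.0, 20))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_locked_trials():
    """Noise-free trials with perfect phase locking at 2 Hz."""
    truth = synth.GroundTruth(
        phase_lock_strength=1.0, noise_sd=0.0, alpha_amp=0.0,
        pac_amp=0.0, pac_modulation=0.0, alpha_power_change=0.0, seed=7,
    )
    return synth.gen_trials(truth, n_trials=6, n_channels=2, fs=256.0)
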