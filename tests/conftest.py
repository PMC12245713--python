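import numpy as np
import pytest

from sleepstager.io_edf import Hypnogram, Recording
from sleepstager.model import ModelConfig
from sleepstager.synthetic import SynthParams, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A miniature network: fast enough for per-test forward/backward passes."""
    return ModelConfig(epoch_samples=80, block_channels=(4, 6, 6),
                       block_kernels=(8, 5, 3), lstm_dim=8, window_k=3, seed=7)


@pytest.fixture
def random_hypnogram(rng):
    def make(n, epoch_length_s=10.0, symbols=("P", "S", "W"), subject="subj"):
        stages = np.array(symbols, dtype="U1")[rng.integers(0, len(symbols), n)]
        return Hypnogram(subject_id=subject, epoch_length_s=epoch_length_s,
                         stages=stages)
    return make


@pytest.fixture(scope="session")
def small_subject():
    """One 10-minute synthetic subject at the native 500 Hz (cached per session)."""
    params = SynthParams()
    rec, hyp = generate_subject(params, 60, seed=424242, subject_id="rat0")
    return rec, hyp
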