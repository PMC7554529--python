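import numpy as np
import pytest

from midecode import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 5 sessions x 6 trials of strongly modulated EEG —
    enough structure for smoke/determinism tests, small enough to train in
    seconds."""
    config = SynthConfig(erd_depth=0.8, snr=1.5, seed=5)
    return generate_dataset(2, 6, 5, config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
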