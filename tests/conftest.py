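import numpy as np
import pytest

from semgst import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """A short cohort configuration used across unit tests: 4 gesture
    classes, 3 repetitions, 1 s gestures / 0.64 s rests at 100 Hz."""
    return SynthConfig(n_channels=10, fs=100.0, n_classes=4, n_repetitions=3,
                       gesture_dur=1000.0, rest_dur=640.0, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_synth_config):
    return generate_recording(small_synth_config, "S01")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
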