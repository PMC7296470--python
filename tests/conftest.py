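import numpy as np
import pytest

from parwelch import SignalChannel, WelchConfig


@pytest.fixture
def defaults() -> WelchConfig:
    """Canonical EEG settings: L=64, 32-sample overlap, symmetric Hamming."""
    return WelchConfig()


@pytest.fixture
def make_channel():
    """Factory for seeded Gaussian-noise channels."""

    def _make(seed: int, n_samples: int = 256, fs: float = 256.0, label: str = "ch00"):
        rng = np.random.default_rng(seed)
        return SignalChannel(label=label, samples=rng.normal(size=n_samples), fs=fs)

    return _make
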