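import numpy as np
import pytest

from ecoeq import AudioSegment, Spectrogram

FS = 48000


@pytest.fixture
def sine_1khz():
    t = np.arange(FS) / FS
    return AudioSegment(0.5 * np.sin(2 * np.pi * 1000.0 * t), FS, "sine-1k")


@pytest.fixture
def white_noise_10s():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(10 * FS)
    return AudioSegment(0.1 * x / np.sqrt(np.mean(x**2)), FS, "wn-10s")


def random_spectrogram(seed: int, n_freqs: int = 16, n_times: int = 16) -> Spectrogram:
    """A 16x16 random spectrogram on a 16 Hz grid (fs=480, nfft=30)."""
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.0, 1.0, size=(n_freqs, n_times))
    amp[rng.uniform(size=amp.shape) < 0.1] = 0.0  # sprinkle dead cells
    freqs = np.arange(n_freqs) * 16.0
    times = (np.arange(n_times) + 0.5) * (30 / 480)
    return Spectrogram(freqs=freqs, times=times, amp=amp, nfft=30, sample_rate=480)
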