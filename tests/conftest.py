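import numpy as np
import pytest

from eegapm import EEGRecord, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def sine_record(freq_hz, fs=256.0, seconds=15.0, n_channels=19, amplitude=1.0):
    """A record with the same pure sine on every channel."""
    t = np.arange(int(fs * seconds)) / fs
    sig = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecord(np.tile(sig, (n_channels, 1)), fs)


def fft_amplitude(x, freq_hz, fs):
    """Amplitude of a sinusoidal component, Hann-windowed FFT oracle."""
    w = np.hanning(len(x))
    spec = np.fft.rfft(x * w)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return 2.0 * np.abs(spec[np.argmin(np.abs(freqs - freq_hz))]) / w.sum()


def steady_interior(x, fs, margin_s=4.0):
    """Drop filter edge transients at both ends."""
    m = int(margin_s * fs)
    return x[m:-m]


@pytest.fixture
def rank1_segment(rng):
    """Rank-1 clean matrix (shared 10 Hz sine, per-channel gains) + metadata."""
    fs = 256.0
    t = np.arange(int(15 * fs)) / fs
    gains = rng.uniform(0.5, 2.0, 19)[:, None]
    clean = gains * np.sin(2 * np.pi * 10 * t)[None, :]
    return clean, fs
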