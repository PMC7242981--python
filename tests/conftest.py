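import numpy as np
import pytest

from vocspan.vocoder import AudioSignal

RATE = 44100.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq: float, duration: float = 0.5, rate: float = RATE,
              amplitude: float = 0.5) -> AudioSignal:
    t = np.arange(int(duration * rate)) / rate
    return AudioSignal(samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate)


def make_am_tone(carrier: float, mod_rate: float, depth: float = 1.0,
                 duration: float = 1.0, rate: float = RATE) -> AudioSignal:
    """Sinusoidally amplitude-modulated tone with the given modulation depth."""
    t = np.arange(int(duration * rate)) / rate
    envelope = 1.0 + depth * np.sin(2 * np.pi * mod_rate * t)
    return AudioSignal(samples=0.3 * envelope * np.sin(2 * np.pi * carrier * t),
                       rate=rate)


def band_energy_fraction(signal: AudioSignal, low: float, high: float) -> float:
    """Fraction of total spectral energy inside [low, high) Hz."""
    spectrum = np.abs(np.fft.rfft(signal.samples)) ** 2
    freqs = np.fft.rfftfreq(len(signal.samples), d=1.0 / signal.rate)
    total = spectrum.sum()
    return float(spectrum[(freqs >= low) & (freqs < high)].sum() / total)


# deterministic hypothesis runs
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=200)
settings.load_profile("deterministic")
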