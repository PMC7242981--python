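"""Noise-band channel vocoding of speech audio.

A channel vocoder divides a speech signal into contiguous frequency bands,
extracts the slow amplitude envelope of each band, and re-imposes those
envelopes on band-limited noise carriers. Summing the modulated carriers
yields a signal that preserves temporal-envelope cues but discards spectral
fine structure — the standard acoustic simulation of cochlear-implant
hearing. Spectral resolution is controlled by the number of channels.

Analysis bands are rectangular (brick-wall) filters whose edges are
approximately equally spaced along the cochlea according to the Greenwood
frequency–place map. The canonical 17-edge layout spanning 100–10000 Hz is
provided as :data:`STUDY_EDGES`; merging adjacent bands produces the 8- and
4-channel variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfilt, sosfiltfilt

__all__ = [
    "STUDY_EDGES",
    "AudioSignal",
    "VocoderSpec",
    "greenwood_frequency",
    "greenwood_position",
    "build_filterbank",
    "brickwall_bandpass",
    "extract_envelope",
    "vocode",
    "preprocess_recording",
    "read_wav",
    "write_wav",
]

#: Canonical 17 band-edge frequencies (Hz) for the 16-channel analysis
#: filterbank, 100–10000 Hz, approximately equally spaced on the Greenwood
#: map. Adjacent bands are merged pairwise for 8 channels and in groups of
#: four for 4 channels.
STUDY_EDGES: tuple[float, ...] = (
    100.0, 164.0, 245.0, 346.0, 475.0, 637.0, 842.0, 1099.0, 1425.0,
    1835.0, 2352.0, 3005.0, 3828.0, 4866.0, 6175.0, 7826.0, 10000.0,
)

# Greenwood human cochlear map F = A * (10**(a*x) - k), x in [0, 1] from
# apex to base.
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 2.1
_GREENWOOD_K = 0.88


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal: sample values plus a sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D samples)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self) else 0.0


@dataclass(frozen=True)
class VocoderSpec:
    """Configuration of one vocoder condition.

    Parameters
    ----------
    edges
        Strictly increasing band-edge frequencies in Hz; ``len(edges) - 1``
        channels.
    envelope_cutoff
        Low-pass cutoff (Hz) applied to the Hilbert envelope of each band.
    envelope_order
        Order of the Butterworth envelope smoothing filter.
    carrier
        Carrier type; only ``"noise"`` is supported.
    seed
        Seed for the carrier noise generator. Identical (signal, spec)
        pairs produce bit-identical output.
    """

    edges: tuple[float, ...]
    envelope_cutoff: float = 300.0
    envelope_order: int = 4
    carrier: str = "noise"
    seed: int = 0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ValueError("need at least two edges (one channel)")
        if edges[0] < 0:
            raise ValueError("first edge must be >= 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if self.envelope_cutoff <= 0:
            raise ValueError("envelope_cutoff must be positive")
        if self.carrier != "noise":
            raise ValueError(f"unsupported carrier {self.carrier!r}")
        object.__setattr__(self, "edges", edges)

    @property
    def n_channels(self) -> int:
        return len(self.edges) - 1

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    @classmethod
    def study_preset(cls, n_channels: int, seed: int = 0) -> "VocoderSpec":
        """The 16/8/4-channel study condition built from :data:`STUDY_EDGES`."""
        bands = build_filterbank(n_channels, STUDY_EDGES)
        edges = [bands[0][0]] + [hi for _, hi in bands]
        return cls(edges=tuple(edges), seed=seed)

    @classmethod
    def from_json(cls, path: str | Path) -> "VocoderSpec":
        cfg = json.loads(Path(path).read_text())
        return cls(
            edges=tuple(cfg["edges"]),
            envelope_cutoff=cfg.get("envelope_cutoff", 300.0),
            envelope_order=cfg.get("envelope_order", 4),
            carrier=cfg.get("carrier", "noise"),
            seed=cfg.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "edges": list(self.edges),
            "envelope_cutoff": self.envelope_cutoff,
            "envelope_order": self.envelope_order,
            "carrier": self.carrier,
            "seed": self.seed,
        }, indent=2))


def greenwood_frequency(position: float | np.ndarray) -> float | np.ndarray:
    """Characteristic frequency (Hz) at relative cochlear place ``position``.

    Uses the standard human map ``F = A (10^{a x} - k)`` with A = 165.4,
    a = 2.1, k = 0.88, where x runs from 0 (apex, low frequency) to 1
    (base, high frequency).
    """
    position = np.asarray(position, dtype=float)
    if np.any((position < 0) | (position > 1)):
        raise ValueError("cochlear position must lie in [0, 1]")
    freq = _GREENWOOD_A * (10.0 ** (_GREENWOOD_ALPHA * position) - _GREENWOOD_K)
    return float(freq) if freq.ndim == 0 else freq


def greenwood_position(frequency: float | np.ndarray) -> float | np.ndarray:
    """Inverse Greenwood map: relative cochlear place of ``frequency`` Hz."""
    frequency = np.asarray(frequency, dtype=float)
    arg = frequency / _GREENWOOD_A + _GREENWOOD_K
    if np.any(arg <= 0):
        raise ValueError("frequency below the apical limit of the map")
    pos = np.log10(arg) / _GREENWOOD_ALPHA
    if np.any((pos < -1e-12) | (pos > 1 + 1e-12)):
        raise ValueError("frequency outside the cochlear range of the map")
    pos = np.clip(pos, 0.0, 1.0)
    return float(pos) if pos.ndim == 0 else pos


def build_filterbank(
    n_channels: int, master_edges: tuple[float, ...] | list[float] = STUDY_EDGES
) -> list[tuple[float, float]]:
    """Channel (low, high) bands formed by merging adjacent master bands.

    The master edge list defines the finest filterbank; lower channel counts
    are obtained by combining adjacent bands, so ``len(master_edges) - 1``
    must be divisible by ``n_channels``. Bands tile the full range with no
    gaps or overlaps.
    """
    edges = [float(e) for e in master_edges]
    n_master = len(edges) - 1
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_master < 1 or n_master % n_channels != 0:
        raise ValueError(
            f"{n_master} master bands cannot be merged into {n_channels} channels"
        )
    step = n_master // n_channels
    kept = edges[::step]
    return list(zip(kept[:-1], kept[1:]))


def _check_band(band: tuple[float, float], rate: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not 0 <= low < high:
        raise ValueError(f"invalid band ({low}, {high})")
    if high > rate / 2:
        raise ValueError(f"band edge {high} Hz above Nyquist ({rate / 2} Hz)")
    return low, high


def brickwall_bandpass(samples: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Rectangular (brick-wall) band-pass via FFT bin masking.

    Bins with ``low <= f < high`` are kept, all others zeroed. The sharp
    transfer function keeps adjacent channels exactly complementary, so the
    filterbank tiles the analysis range without spectral overlap.
    """
    low, high = _check_band(band, rate)
    spectrum = np.fft.rfft(samples)
    freqs = np.fft.rfftfreq(len(samples), d=1.0 / rate)
    mask = (freqs >= low) & (freqs < high)
    return np.fft.irfft(spectrum * mask, n=len(samples))


def extract_envelope(
    signal: AudioSignal, band: tuple[float, float], spec: VocoderSpec
) -> np.ndarray:
    """Smoothed amplitude envelope of one analysis band.

    The band is isolated with a brick-wall filter, its analytic amplitude
    taken via the Hilbert transform, and the result low-pass filtered with a
    causal Butterworth filter at ``spec.envelope_cutoff``. Small negative
    excursions introduced by the smoothing filter are clamped to zero.
    """
    _check_band(band, signal.rate)
    if len(signal) == 0:
        raise ValueError("empty signal")
    band_signal = brickwall_bandpass(signal.samples, signal.rate, band)
    envelope = np.abs(hilbert(band_signal))
    sos = butter(spec.envelope_order, spec.envelope_cutoff, btype="low",
                 fs=signal.rate, output="sos")
    smoothed = sosfilt(sos, envelope)
    return np.maximum(smoothed, 0.0)


def vocode(signal: AudioSignal, spec: VocoderSpec) -> AudioSignal:
    """Noise-band vocode ``signal`` according to ``spec``.

    For each channel: band-pass the input, extract and smooth the envelope,
    multiply it with an independent unit-RMS band-limited Gaussian noise
    carrier, and sum across channels. The summed output is rescaled to the
    input's overall RMS. Deterministic for a fixed (signal, spec) pair:
    carriers are drawn from one generator seeded with ``spec.seed``, in
    channel order from low to high frequency.
    """
    if len(signal) == 0:
        raise ValueError("cannot vocode an empty signal")
    top_edge = spec.edges[-1]
    if signal.rate < 2 * top_edge:
        raise ValueError(
            f"sampling rate {signal.rate} Hz too low for top edge {top_edge} Hz"
        )
    rng = np.random.default_rng(spec.seed)
    output = np.zeros(len(signal))
    for band in spec.bands:
        envelope = extract_envelope(signal, band, spec)
        carrier = rng.standard_normal(len(signal))
        carrier = brickwall_bandpass(carrier, signal.rate, band)
        carrier_rms = np.sqrt(np.mean(np.square(carrier)))
        if carrier_rms > 0:
            carrier /= carrier_rms
        output += envelope * carrier
    in_rms = signal.rms()
    out_rms = np.sqrt(np.mean(np.square(output)))
    if out_rms > 0:
        output *= in_rms / out_rms
    return AudioSignal(samples=output, rate=signal.rate)


def preprocess_recording(
    signal: AudioSignal,
    low: float = 80.0,
    high: float = 20000.0,
    order: int = 4,
    peak_target: float = 0.9,
) -> AudioSignal:
    """Band-pass and peak-normalize a raw recording.

    Applies a Butterworth band-pass of the given order both forward and in
    reverse (zero phase, no group delay), then scales the waveform so its
    peak absolute amplitude equals ``peak_target``.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= signal.rate / 2:
        raise ValueError(f"high edge {high} Hz must be below Nyquist ({signal.rate / 2} Hz)")
    sos = butter(order, [low, high], btype="band", fs=signal.rate, output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    peak = np.max(np.abs(filtered))
    if peak > 0:
        filtered = filtered * (peak_target / peak)
    return AudioSignal(samples=filtered, rate=signal.rate)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as an AudioSignal.

    Integer formats are scaled to [-1, 1).
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return AudioSignal(samples=samples, rate=float(rate))


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write an AudioSignal to WAV as float32 (default) or 16-bit PCM."""
    if subtype == "float32":
        wavfile.write(str(path), int(signal.rate), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0 - 1.0 / 32768)
        wavfile.write(str(path), int(signal.rate), (clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
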