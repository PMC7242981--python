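"""Noise-band vocoder: Greenwood map, filterbank, envelopes, synthesis."""

import numpy as np
import pytest

from conftest import RATE, band_energy_fraction, make_am_tone, make_tone
from vocspan.vocoder import (
    STUDY_EDGES,
    AudioSignal,
    VocoderSpec,
    build_filterbank,
    extract_envelope,
    greenwood_frequency,
    greenwood_position,
    preprocess_recording,
    read_wav,
    vocode,
    write_wav,
)


class TestGreenwood:
    def test_round_trip_identity(self):
        positions = np.linspace(0.0, 1.0, 101)
        recovered = greenwood_position(greenwood_frequency(positions))
        assert np.allclose(recovered, positions, rtol=1e-9, atol=1e-12)

    def test_apex_frequency_matches_map_constants(self):
        # F(0) = A (1 - k) = 165.4 * 0.12
        assert greenwood_frequency(0.0) == pytest.approx(19.848, abs=1e-3)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 500)
        freqs = greenwood_frequency(grid)
        assert np.all(np.diff(freqs) > 0)
        assert greenwood_frequency(0.3) < greenwood_frequency(0.31)

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            greenwood_frequency(bad)

    def test_study_edges_near_equally_spaced_on_map(self):
        """The 17 preset edges cover ~equal cochlear distance per channel."""
        positions = greenwood_position(np.array(STUDY_EDGES))
        steps = np.diff(positions)
        mean_step = steps.mean()
        assert np.abs(steps - mean_step).max() < 0.05 * mean_step


class TestFilterbank:
    def test_16_channel_preset_returns_printed_edges(self):
        bands = build_filterbank(16)
        assert bands[0] == (100.0, 164.0)
        edges = [bands[0][0]] + [hi for _, hi in bands]
        assert edges == list(STUDY_EDGES)

    def test_8_channel_merges_adjacent_pairs(self):
        bands = build_filterbank(8)
        edges = {bands[0][0]} | {hi for _, hi in bands}
        assert edges == {100, 245, 475, 842, 1425, 2352, 3828, 6175, 10000}

    def test_4_channel_merges_quadruples(self):
        bands = build_filterbank(4)
        edges = {bands[0][0]} | {hi for _, hi in bands}
        assert edges == {100, 475, 1425, 3828, 10000}

    @pytest.mark.parametrize("n", [4, 8, 16])
    def test_bands_tile_without_gaps(self, n):
        bands = build_filterbank(n)
        assert bands[0][0] == 100.0 and bands[-1][1] == 10000.0
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            assert hi == lo

    def test_non_divisible_merge_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(5)


class TestEnvelope:
    SPEC = VocoderSpec.study_preset(16)

    def test_silence_gives_zero_envelope(self):
        silence = AudioSignal(samples=np.zeros(4096), rate=RATE)
        env = extract_envelope(silence, (842.0, 1099.0), self.SPEC)
        assert env.shape == (4096,)
        assert np.allclose(env, 0.0)

    def test_recovers_slow_amplitude_modulation(self):
        signal = make_am_tone(carrier=1000.0, mod_rate=10.0, depth=1.0)
        env = extract_envelope(signal, (842.0, 1099.0), self.SPEC)
        assert env.min() >= 0.0
        core = env[4000:-4000]  # discard filter transients
        spectrum = np.abs(np.fft.rfft(core - core.mean()))
        freqs = np.fft.rfftfreq(core.size, d=1.0 / RATE)
        peak = freqs[np.argmax(spectrum)]
        assert peak == pytest.approx(10.0, abs=1.0)
        depth = (core.max() - core.min()) / (core.max() + core.min())
        assert depth >= 0.9

    def test_unmodulated_tone_envelope_is_flat(self):
        signal = make_tone(950.0, duration=1.0)
        env = extract_envelope(signal, (842.0, 1099.0), self.SPEC)
        core = env[4000:-4000]
        assert core.std() / core.mean() < 0.05

    @pytest.mark.parametrize("mod_rate", [5.0, 20.0, 50.0])
    def test_imposed_and_recovered_envelopes_correlate(self, mod_rate):
        signal = make_am_tone(carrier=1000.0, mod_rate=mod_rate, depth=0.8)
        env = extract_envelope(signal, (842.0, 1099.0), self.SPEC)
        t = np.arange(len(signal)) / RATE
        imposed = 1.0 + 0.8 * np.sin(2 * np.pi * mod_rate * t)
        # the causal smoothing filter delays the envelope by ~1 ms; align
        # within that delay before correlating
        max_lag = int(0.005 * RATE)
        best = max(
            np.corrcoef(env[4000 + lag:-4000 + lag or None],
                        imposed[4000:-4000])[0, 1]
            for lag in range(0, max_lag + 1, 4)
        )
        assert best >= 0.95

    def test_fast_modulation_attenuated_above_cutoff(self):
        signal = make_am_tone(carrier=3000.0, mod_rate=600.0, depth=1.0)
        env = extract_envelope(signal, (2352.0, 3828.0), self.SPEC)
        core = env[4000:-4000]
        depth = (core.max() - core.min()) / (core.max() + core.min())
        assert depth <= 0.2

    def test_band_above_nyquist_rejected(self):
        signal = make_tone(1000.0, rate=8000.0)
        with pytest.raises(ValueError):
            extract_envelope(signal, (3000.0, 5000.0), self.SPEC)


class TestVocode:
    def test_silence_in_silence_out(self):
        silence = AudioSignal(samples=np.zeros(8192), rate=RATE)
        out = vocode(silence, VocoderSpec.study_preset(4))
        assert len(out) == len(silence)
        assert np.allclose(out.samples, 0.0)

    def test_energy_stays_in_source_channel(self, rng):
        spec = VocoderSpec.study_preset(8, seed=1)
        low, high = spec.bands[3]  # 842-1425 Hz
        noise = rng.standard_normal(int(RATE))
        spectrum = np.fft.rfft(noise)
        freqs = np.fft.rfftfreq(noise.size, d=1.0 / RATE)
        spectrum[(freqs < low) | (freqs >= high)] = 0.0
        signal = AudioSignal(samples=np.fft.irfft(spectrum, n=noise.size), rate=RATE)
        out = vocode(signal, spec)
        assert band_energy_fraction(out, low, high) >= 0.90

    def test_out_of_band_leakage_below_one_percent(self):
        signal = make_am_tone(carrier=1000.0, mod_rate=8.0, depth=0.9)
        for n_channels in (4, 8, 16):
            out = vocode(signal, VocoderSpec.study_preset(n_channels, seed=2))
            assert band_energy_fraction(out, 100.0, 10000.0) >= 0.99

    def test_same_seed_bit_identical(self):
        signal = make_am_tone(carrier=500.0, mod_rate=4.0)
        spec = VocoderSpec.study_preset(8, seed=42)
        first = vocode(signal, spec)
        second = vocode(signal, spec)
        assert np.array_equal(first.samples, second.samples)
        different = vocode(signal, VocoderSpec.study_preset(8, seed=43))
        assert not np.array_equal(first.samples, different.samples)

    def test_output_rms_matches_input(self):
        signal = make_am_tone(carrier=1500.0, mod_rate=6.0)
        out = vocode(signal, VocoderSpec.study_preset(16, seed=0))
        assert out.rms() == pytest.approx(signal.rms(), rel=1e-9)
        assert len(out) == len(signal)

    def test_channel_merge_energy_consistency(self, rng):
        """Summing 16-channel band energies pairwise equals the 8-channel ones."""
        samples = rng.standard_normal(int(RATE / 2))
        signal = AudioSignal(samples=samples, rate=RATE)
        bands16 = build_filterbank(16)
        bands8 = build_filterbank(8)
        energies16 = np.array([
            band_energy_fraction(signal, lo, hi) for lo, hi in bands16])
        energies8 = np.array([
            band_energy_fraction(signal, lo, hi) for lo, hi in bands8])
        assert np.allclose(energies16.reshape(8, 2).sum(axis=1), energies8,
                           rtol=1e-9, atol=1e-12)

    def test_rate_too_low_rejected(self):
        signal = make_tone(1000.0, rate=16000.0)
        with pytest.raises(ValueError):
            vocode(signal, VocoderSpec.study_preset(4))

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            vocode(AudioSignal(samples=np.zeros(0), rate=RATE),
                   VocoderSpec.study_preset(4))


class TestPreprocess:
    def test_peak_normalized_to_target(self):
        signal = make_tone(440.0, amplitude=0.1)
        out = preprocess_recording(signal, 80.0, 20000.0)
        assert np.max(np.abs(out.samples)) == pytest.approx(0.9, rel=1e-9)

    def test_subsonic_component_attenuated(self):
        """A 50 Hz component is suppressed by the doubled 4th-order filter.

        Peak normalization hides absolute gain, so attenuation is measured
        on a composite tone as the 50 Hz band's share relative to an
        in-band 1 kHz component.
        """
        t = np.arange(int(RATE)) / RATE
        composite = AudioSignal(
            samples=0.4 * np.sin(2 * np.pi * 50 * t)
            + 0.4 * np.sin(2 * np.pi * 1000 * t), rate=RATE)
        out = preprocess_recording(composite, 80.0, 20000.0)
        in_frac = band_energy_fraction(composite, 0.0, 65.0)
        out_frac = band_energy_fraction(out, 0.0, 65.0)
        # RMS ratio in the subsonic band shrinks below 15% of its input share
        assert np.sqrt(out_frac / in_frac) < 0.15

    def test_zero_phase_no_lag(self):
        signal = make_am_tone(carrier=1000.0, mod_rate=5.0, duration=0.5)
        out = preprocess_recording(signal, 80.0, 20000.0)
        xcorr = np.correlate(out.samples, signal.samples, mode="full")
        lag = int(np.argmax(xcorr)) - (len(signal) - 1)
        assert lag == 0

    def test_high_edge_above_nyquist_rejected(self):
        signal = make_tone(440.0, rate=16000.0)
        with pytest.raises(ValueError):
            preprocess_recording(signal, 80.0, 9000.0)


class TestWavIO:
    def test_float32_round_trip(self, tmp_path, rng):
        signal = AudioSignal(samples=rng.uniform(-0.5, 0.5, 4410), rate=RATE)
        path = tmp_path / "x.wav"
        write_wav(path, signal)
        back = read_wav(path)
        assert back.rate == RATE
        assert np.allclose(back.samples, signal.samples, atol=1e-7)

    def test_pcm16_round_trip(self, tmp_path):
        signal = make_tone(440.0, duration=0.05)
        path = tmp_path / "x16.wav"
        write_wav(path, signal, subtype="pcm16")
        back = read_wav(path)
        assert np.allclose(back.samples, signal.samples, atol=1e-3)
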