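"""Sigma-clipping thresholds, alpha selection, silence finding, gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibrokit import audio_io, denoise, scenes
from vibrokit.denoise import (
    DEFAULT_ALPHA,
    NoUsableSilence,
    alpha_grid,
    amplitude_threshold,
    denoise_chunk,
    longest_silence,
    noise_spectrum,
    select_alpha,
    spectral_gate,
    _knee_of_counts,
)

FS = 48000


class TestAmplitudeThreshold:
    def test_constant_signal_degenerate(self):
        th = amplitude_threshold(np.full(100, 3.0), alpha=7.0)
        assert th.m == 3.0 and th.sigma == 0.0 and th.T == 3.0

    def test_hand_arithmetic(self):
        # |x| = {1,1,1,3}: m = 1, sigma = sqrt(0.75), T = 1 + 2*sqrt(0.75)
        th = amplitude_threshold(np.array([1.0, -1.0, 1.0, -3.0]), alpha=2.0)
        assert th.m == 1.0
        assert th.sigma == pytest.approx(np.sqrt(0.75))
        assert th.T == pytest.approx(1.0 + 2.0 * np.sqrt(0.75))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_threshold_scales_with_signal(self, k):
        x = np.array([0.5, -1.0, 2.0, 0.1, -0.3])
        assert amplitude_threshold(k * x, 2.5).T == pytest.approx(
            k * amplitude_threshold(x, 2.5).T)

    def test_monotone_in_alpha(self):
        x = np.random.default_rng(0).normal(size=1000)
        Ts = [amplitude_threshold(x, a).T for a in alpha_grid()]
        assert all(b >= a for a, b in zip(Ts, Ts[1:]))


class TestSelectAlpha:
    def test_grid_has_31_values(self):
        g = alpha_grid()
        assert g.size == 31
        assert g[0] == 1.0
        assert g[-1] == pytest.approx(10.0)
        assert np.allclose(np.diff(g), 0.3)

    def test_counts_non_increasing(self):
        x = np.random.default_rng(0).normal(size=10_000)
        scan = select_alpha(x)
        assert np.all(np.diff(scan.counts) <= 0)

    def test_all_zero_signal_default_alpha(self):
        scan = select_alpha(np.zeros(1000))
        assert np.all(scan.counts == 0)
        assert scan.selected_alpha == DEFAULT_ALPHA

    def test_scale_invariance(self):
        x = np.random.default_rng(3).normal(size=20_000)
        x[::500] += 30.0  # sparse spikes
        a = select_alpha(x)
        b = select_alpha(1000.0 * x)
        assert a.selected_alpha == b.selected_alpha
        assert np.array_equal(a.counts, b.counts)

    def test_spikes_on_low_noise_isolated(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.01, 200_000)
        spikes = rng.choice(200_000, size=50, replace=False)
        x[spikes] += 5.0
        scan = select_alpha(x)
        detected = np.flatnonzero(np.abs(x) > scan.threshold.T)
        assert set(detected) == set(spikes)

    def test_linear_counts_fall_back_to_default(self):
        alphas = alpha_grid()
        counts = np.linspace(1000, 0, alphas.size)
        alpha, method = _knee_of_counts(alphas, counts)
        assert alpha == DEFAULT_ALPHA
        assert method == "default"


class TestLongestSilence:
    def test_all_below_threshold_whole_signal(self):
        x = np.full(FS, 0.1)
        s, e = longest_silence(x, FS, T=1.0)
        assert (s, e) == (0.0, 1.0)

    def test_tie_goes_to_earlier_run(self):
        x = np.full(12 * FS, 0.1)
        for sec in (2, 6, 10):  # loud seconds; interior silent runs 3-6, 7-10
            x[sec * FS:(sec + 1) * FS] = 5.0
        s, e = longest_silence(x, FS, T=1.0, min_silence_len=0.5)
        assert e - s == pytest.approx(3.0, abs=0.05)
        assert s == pytest.approx(3.0, abs=0.05)

    def test_no_silence_raises(self):
        x = np.full(FS, 5.0)
        with pytest.raises(NoUsableSilence):
            longest_silence(x, FS, T=1.0)

    def test_too_short_silence_raises(self):
        x = np.full(FS, 5.0)
        x[:FS // 10] = 0.0  # only 0.1 s quiet
        with pytest.raises(NoUsableSilence):
            longest_silence(x, FS, T=1.0, min_silence_len=1.0)

    def test_planted_quiet_gap_recovered(self):
        """A 30-s quiet gap planted in otherwise continuous loud activity is
        returned to within the envelope window."""
        spec = scenes.SceneSpec(
            duration_s=120.0,
            noise_rms_mv=0.1,
            species=[scenes.SpeciesSpec(
                label="sp", center_freq_hz=400.0, amplitude_mv=8.0,
                n_bouts=40, pulses_per_bout=(10, 10),
                within_bout_s=(0.03, 0.01), between_bout_s=(1.5, 0.02),
                bouts_per_activity=100)],
            quiet_gaps=[(60.0, 90.0)],
            gap_noise_factor=0.0,
            seed=2,
        )
        wave, truth = scenes.render_scene(spec)
        assert truth.pulses["time_s"].max() > 100.0  # activity spans the file
        s, e = longest_silence(wave.samples, FS, T=1.0)
        # the recovered stretch contains the planted gap and may extend into
        # the signal-free between-bout margins (~1.5 s) on either side
        assert s <= 60.0 and e >= 90.0
        assert s == pytest.approx(60.0, abs=2.0)
        assert e == pytest.approx(90.0, abs=2.0)


class TestNoiseSpectrum:
    def test_white_noise_flat(self):
        x = np.random.default_rng(0).standard_normal(10 * FS)
        prof = noise_spectrum(x, FS)
        inner = prof.mean_mag[1:-1]  # edge bins carry half-width bands
        assert inner.max() / inner.min() < 2.0

    def test_tone_peaks_at_right_bin(self):
        t = np.arange(2 * FS) / FS
        prof = noise_spectrum(np.sin(2 * np.pi * 400 * t), FS)
        assert abs(prof.freqs[np.argmax(prof.mean_mag)] - 400) <= FS / 512

    def test_zeros_profile_is_zero(self):
        prof = noise_spectrum(np.zeros(FS), FS)
        assert np.all(prof.mean_mag == 0)

    def test_too_short_segment_errors(self):
        with pytest.raises(ValueError):
            noise_spectrum(np.zeros(100), FS, n_fft=512)


class TestSpectralGate:
    @pytest.fixture(scope="class")
    def noise_and_profile(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(10 * FS)
        prof = noise_spectrum(noise[:5 * FS], FS)
        return rng, noise, prof

    def test_pure_noise_reduced_10db(self, noise_and_profile):
        _, noise, prof = noise_and_profile
        x = noise[5 * FS:]
        out = spectral_gate(x, prof)
        reduction = 20 * np.log10(
            np.sqrt(np.mean(x ** 2)) / max(np.sqrt(np.mean(out ** 2)), 1e-12))
        assert reduction >= 10.0

    def test_strong_tone_preserved_within_3db(self, noise_and_profile):
        rng, _, prof = noise_and_profile
        t = np.arange(5 * FS) / FS
        fbin = int(round(400 / (FS / 512)))
        gate = prof.mean_mag[fbin] + 1.5 * prof.std_mag[fbin]
        amp = 10 * gate / 128  # cell magnitude 20 dB above the gate
        x = amp * np.sin(2 * np.pi * 400 * t) + rng.standard_normal(5 * FS)
        out = spectral_gate(x, prof)
        ref = np.exp(-2j * np.pi * 400 * t)
        a_out = 2 * np.abs(np.mean(out * ref))
        assert 20 * np.abs(np.log10(a_out / amp)) <= 3.0

    def test_zero_input_zero_output(self, noise_and_profile):
        _, _, prof = noise_and_profile
        out = spectral_gate(np.zeros(FS), prof)
        assert np.all(out == 0)
        assert out.size == FS

    def test_length_preserved(self, noise_and_profile):
        _, noise, prof = noise_and_profile
        n = 3 * FS + 1234
        assert spectral_gate(noise[:n], prof).size == n


class TestDenoiseChunk:
    def test_snr_improves_6db(self, short_scene):
        spec, wave, truth, _ = short_scene
        result = denoise_chunk(audio_io.RecordingChunk(waveform=wave))
        assert not result.skipped
        mask = np.zeros(wave.samples.size, dtype=bool)
        for t in truth.pulses["time_s"]:
            i = int(t * FS)
            mask[max(0, i - 2400):i + 4800] = True

        def snr(x):
            return 10 * np.log10(
                np.mean(x[mask] ** 2) / max(np.mean(x[~mask] ** 2), 1e-30))

        post = result.chunk.waveform.samples
        assert snr(post) >= snr(wave.samples) + 6.0

    def test_silent_chunk_flagged_unchanged(self):
        w = audio_io.Waveform(np.zeros(2 * FS), FS)
        result = denoise_chunk(audio_io.RecordingChunk(waveform=w))
        assert result.skipped
        assert np.array_equal(result.chunk.waveform.samples, w.samples)

    def test_deterministic(self, short_scene):
        _, wave, _, _ = short_scene
        c = audio_io.RecordingChunk(waveform=wave)
        a = denoise_chunk(c).chunk.waveform.samples
        b = denoise_chunk(c).chunk.waveform.samples
        assert np.array_equal(a, b)

    def test_sample_count_unchanged(self, short_scene):
        _, wave, _, _ = short_scene
        result = denoise_chunk(audio_io.RecordingChunk(waveform=wave))
        assert result.chunk.waveform.samples.size == wave.samples.size
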