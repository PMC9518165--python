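"""Preprocessing: loading, pre-emphasis, framing, power spectra."""

import numpy as np
import pytest
from scipy.io import wavfile

from laughpd import (
    AudioClip,
    ConfigError,
    FramingConfig,
    InputError,
    frame_and_window,
    load_clip,
    power_spectra,
    pre_emphasize,
    preprocess,
)


def _write_wav(path, rate, samples):
    wavfile.write(path, rate, (np.clip(samples, -1, 1) * 32767).astype(np.int16))


class TestLoadClip:
    def test_resample_conserves_duration(self, tmp_path):
        t = np.arange(44100) / 44100
        _write_wav(tmp_path / "a.wav", 44100, 0.5 * np.sin(2 * np.pi * 440 * t))
        clip = load_clip(tmp_path / "a.wav", 16000)
        assert clip.samples.size == 16000
        assert clip.sample_rate == 16000

    def test_native_rate_is_not_resampled(self, tmp_path):
        rng = np.random.default_rng(0)
        x = 0.3 * rng.standard_normal(8000)
        _write_wav(tmp_path / "b.wav", 16000, x)
        clip = load_clip(tmp_path / "b.wav", 16000)
        # bit-identical up to the int16 quantization of the file itself
        expected = (np.clip(x, -1, 1) * 32767).astype(np.int16) / 32768.0
        np.testing.assert_array_equal(clip.samples, expected)

    def test_stereo_identical_channels_average_to_mono(self, tmp_path):
        rng = np.random.default_rng(1)
        x = (np.clip(0.3 * rng.standard_normal(4000), -1, 1) * 32767).astype(np.int16)
        wavfile.write(tmp_path / "c.wav", 16000, np.column_stack([x, x]))
        clip = load_clip(tmp_path / "c.wav", 16000)
        np.testing.assert_allclose(clip.samples, x / 32768.0)

    def test_missing_file_raises_input_error(self, tmp_path):
        with pytest.raises(InputError):
            load_clip(tmp_path / "nope.wav")


class TestPreEmphasis:
    def test_constant_input(self):
        clip = AudioClip(np.array([1.0, 1.0, 1.0]), 16000)
        out = pre_emphasize(clip, 0.97)
        np.testing.assert_allclose(out.samples, [1.0, 0.03, 0.03])

    def test_small_k_approaches_identity(self):
        clip = AudioClip(np.linspace(-1, 1, 100), 16000)
        out = pre_emphasize(clip, 1e-9)
        np.testing.assert_allclose(out.samples, clip.samples, atol=1e-8)

    def test_transfer_function_matches_closed_form(self):
        # impulse response is (1, -k); its DFT magnitude must equal
        # |1 - k e^{-jw}| on the frequency grid
        k = 0.97
        impulse = AudioClip(np.eye(1, 512)[0], 16000)
        h = np.fft.rfft(pre_emphasize(impulse, k).samples)
        w = 2 * np.pi * np.arange(257) / 512
        expected = np.abs(1 - k * np.exp(-1j * w))
        np.testing.assert_allclose(np.abs(h), expected, rtol=1e-12)
        assert np.abs(h)[0] == pytest.approx(1 - k)
        assert np.abs(h)[-1] == pytest.approx(1 + k)

    @pytest.mark.parametrize("k", [0.0, 1.0, -0.5, 2.0])
    def test_k_out_of_range_rejected(self, k):
        clip = AudioClip(np.ones(10), 16000)
        with pytest.raises(ConfigError):
            pre_emphasize(clip, k)


class TestFraming:
    def test_frame_count_matches_brute_force(self, framing):
        clip = AudioClip(np.ones(16000), 16000)
        frames = frame_and_window(clip, framing)
        w, h = 400, 240
        brute = sum(1 for start in range(0, 16001 - w, h))
        assert frames.shape == (brute, w)
        assert brute == 66

    def test_single_frame_boundary(self, framing):
        clip = AudioClip(np.ones(400), 16000)
        assert frame_and_window(clip, framing).shape[0] == 1

    def test_constant_input_yields_window(self, framing):
        clip = AudioClip(np.ones(400), 16000)
        np.testing.assert_allclose(frame_and_window(clip, framing)[0], np.hanning(400))

    def test_too_short_clip_names_minimum(self, framing):
        with pytest.raises(InputError, match="25"):
            frame_and_window(AudioClip(np.ones(399), 16000), framing)

    def test_hop_shift_property(self, framing, rng):
        x = rng.standard_normal(16000)
        clip = AudioClip(x, 16000)
        shifted = AudioClip(np.concatenate([rng.standard_normal(240), x]), 16000)
        f1 = frame_and_window(clip, framing)
        f2 = frame_and_window(shifted, framing)
        np.testing.assert_allclose(f2[1 : f1.shape[0]], f1[: f1.shape[0] - 1], atol=1e-12)


class TestPowerSpectra:
    def test_zero_frame(self, framing):
        spec = power_spectra(np.zeros((1, 400)), framing)
        assert np.all(spec.power == 0)

    def test_impulse_is_flat(self, framing):
        frame = np.zeros((1, 400))
        frame[0, 0] = 1.0
        spec = power_spectra(frame, framing)
        np.testing.assert_allclose(spec.power, 1.0)

    def test_sine_peaks_at_expected_bin_and_matches_naive_dft(self, framing):
        t = np.arange(400) / 16000
        frame = (np.sin(2 * np.pi * 1000 * t) * np.hanning(400))[None, :]
        spec = power_spectra(frame, framing)
        assert np.argmax(spec.power[0]) == 32
        padded = np.concatenate([frame[0], np.zeros(112)])
        n = np.arange(512)
        naive = np.array(
            [np.abs(np.sum(padded * np.exp(-2j * np.pi * k * n / 512))) ** 2 for k in range(257)]
        )
        np.testing.assert_allclose(spec.power[0], naive, rtol=1e-9, atol=1e-12)

    def test_bin_frequencies(self, framing):
        spec = power_spectra(np.zeros((1, 400)), framing)
        np.testing.assert_allclose(spec.bin_hz, np.arange(257) * 31.25)

    def test_parseval(self, framing, rng):
        frames = rng.standard_normal((5, 400))
        spec = power_spectra(frames, framing)
        n = framing.dft_size
        # full-spectrum energy from the one-sided power rows
        full = spec.power[:, 0] + spec.power[:, -1] + 2 * spec.power[:, 1:-1].sum(axis=1)
        energy = (frames**2).sum(axis=1)
        np.testing.assert_allclose(full / n, energy, rtol=1e-6)

    def test_dft_smaller_than_frame_rejected(self):
        cfg = FramingConfig(dft_size=256)
        with pytest.raises(ConfigError):
            power_spectra(np.zeros((1, 400)), cfg)


def test_preprocess_deterministic(framing, rng):
    x = rng.standard_normal(8000)
    clip = AudioClip(x, 16000)
    s1 = preprocess(clip, framing)
    s2 = preprocess(clip, framing)
    np.testing.assert_array_equal(s1.power, s2.power)
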