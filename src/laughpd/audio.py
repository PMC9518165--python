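"""Audio loading and short-time spectral analysis of laugh bouts.

A laugh clip is turned into per-frame power spectra in three steps:
first-order pre-emphasis (a high-pass FIR that offsets the glottal
spectral tilt), division into short overlapping Hanning-windowed frames
over which the signal is treated as stationary, and a DFT of each frame.
The defaults — 16 kHz audio, 25 ms windows with 10 ms overlap (15 ms
hop), pre-emphasis k = 0.97, 512-point DFT — are the standard operating
point of the cepstral pipeline built on top of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import ConfigError, InputError

DEFAULT_RATE = 16_000


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform with amplitudes in [-1, 1] plus study labels."""

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    class_label: str = "unknown"  # {"healthy", "pd", "unknown"}
    sex: str = "unknown"  # {"m", "f", "unknown"}
    clip_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise InputError("AudioClip requires a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FramingConfig:
    """Short-time analysis parameters.

    window_ms / overlap_ms follow the convention that *overlap* is the
    shared duration between consecutive windows, so the hop is
    window_ms - overlap_ms (15 ms at the defaults).
    """

    window_ms: float = 25.0
    overlap_ms: float = 10.0
    preemph_k: float = 0.97
    dft_size: int = 512
    window_shape: str = "hanning"

    def __post_init__(self) -> None:
        if not 0 < self.overlap_ms < self.window_ms:
            raise ConfigError(
                f"overlap_ms must lie in (0, window_ms); got overlap={self.overlap_ms},"
                f" window={self.window_ms}"
            )
        if not 0 < self.preemph_k < 1:
            raise ConfigError(f"preemph_k must lie in (0, 1), got {self.preemph_k}")
        if self.window_shape != "hanning":
            raise ConfigError(f"unsupported window shape {self.window_shape!r}")

    def window_samples(self, rate: int) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def hop_samples(self, rate: int) -> int:
        return self.window_samples(rate) - int(round(self.overlap_ms * rate / 1000.0))


@dataclass(frozen=True)
class SpectrogramFrames:
    """Per-frame one-sided power spectra |X(j)|^2, j = 0..dft_size/2."""

    power: np.ndarray  # (T, dft_size // 2 + 1)
    bin_hz: np.ndarray  # (dft_size // 2 + 1,)
    frame_times: np.ndarray  # (T,) frame start times in seconds
    sample_rate: int = DEFAULT_RATE
    dft_size: int = 512

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


def load_clip(
    path: str | Path,
    target_rate: int = DEFAULT_RATE,
    *,
    subject_id: str = "",
    class_label: str = "unknown",
    sex: str = "unknown",
    clip_id: str = "",
) -> AudioClip:
    """Read a PCM WAV file as a mono clip at ``target_rate``.

    Stereo channels are averaged; integer PCM is scaled to [-1, 1] by its
    type's full-scale value; resampling uses a polyphase anti-aliasing
    filter and only runs when the file rate differs from the target.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no samples")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if rate != target_rate:
        g = np.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    if samples.size == 0:
        raise InputError(f"WAV file {path} is empty after resampling")
    return AudioClip(
        samples=samples,
        sample_rate=target_rate,
        subject_id=subject_id,
        class_label=class_label,
        sex=sex,
        clip_id=clip_id or path.stem,
    )


def save_clip(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV."""
    samples = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(Path(path), clip.sample_rate, (samples * 32767.0).astype(np.int16))


def pre_emphasize(clip: AudioClip, k: float = 0.97) -> AudioClip:
    """Apply the first-order high-pass y(n) = x(n) - k*x(n-1), y(0) = x(0)."""
    if not 0 < k < 1:
        raise ConfigError(f"pre-emphasis k must lie in (0, 1), got {k}")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - k * x[:-1]
    return replace(clip, samples=y)


def frame_and_window(clip: AudioClip, cfg: FramingConfig) -> np.ndarray:
    """Slice the clip into overlapping frames and apply a Hanning window.

    Returns a (T, W) matrix with T = floor((L - W) / H) + 1; a trailing
    partial frame is discarded so every frame is full length.
    """
    rate = clip.sample_rate
    w = cfg.window_samples(rate)
    h = cfg.hop_samples(rate)
    n = clip.samples.size
    if n < w:
        raise InputError(
            f"clip of {n} samples is shorter than one analysis window"
            f" ({w} samples = {cfg.window_ms} ms at {rate} Hz)"
        )
    n_frames = (n - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    frames = clip.samples[idx]
    return frames * np.hanning(w)[None, :]


def power_spectra(frames: np.ndarray, cfg: FramingConfig, sample_rate: int = DEFAULT_RATE) -> SpectrogramFrames:
    """One-sided power spectrum |X(j)|^2 of each (already windowed) frame."""
    w = frames.shape[1]
    if cfg.dft_size < w:
        raise ConfigError(f"dft_size {cfg.dft_size} is smaller than the frame length {w}")
    spectrum = np.fft.rfft(frames, n=cfg.dft_size, axis=1)
    power = np.abs(spectrum) ** 2
    bin_hz = np.arange(cfg.dft_size // 2 + 1) * (sample_rate / cfg.dft_size)
    hop = cfg.hop_samples(sample_rate)
    times = np.arange(frames.shape[0]) * hop / sample_rate
    return SpectrogramFrames(
        power=power,
        bin_hz=bin_hz,
        frame_times=times,
        sample_rate=sample_rate,
        dft_size=cfg.dft_size,
    )


def preprocess(clip: AudioClip, cfg: FramingConfig | None = None) -> SpectrogramFrames:
    """Pre-emphasis -> framing/windowing -> power spectra, at one call."""
    cfg = cfg or FramingConfig()
    emphasized = pre_emphasize(clip, cfg.preemph_k)
    frames = frame_and_window(emphasized, cfg)
    return power_spectra(frames, cfg, clip.sample_rate)
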