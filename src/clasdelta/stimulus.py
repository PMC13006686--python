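"""Binaural pink-noise burst synthesis.

The auditory stimulus is a 50 ms burst of pink (1/f) noise with 5 ms
raised-cosine onset/offset ramps, delivered identically to both ears
(diotic).  Sound-pressure calibration is hardware dependent, so the 65 dB
SPL ceiling is carried as metadata only; the digital level is governed by
``level_dbfs``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["StimulusSpec", "synth_pink_burst", "write_wav", "read_wav"]


@dataclass(frozen=True)
class StimulusSpec:
    """Pink-noise burst parameters (durations in ms, level in dBFS)."""

    duration_ms: float = 50.0
    ramp_ms: float = 5.0
    audio_fs: float = 44100.0
    level_dbfs: float = -3.0
    max_spl_db: float = 65.0  # metadata ceiling, not a digital level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.audio_fs <= 0:
            raise ValueError(f"audio_fs must be > 0, got {self.audio_fs}")
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.ramp_ms < 0:
            raise ValueError(f"ramp_ms must be >= 0, got {self.ramp_ms}")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError(
                f"ramps ({self.ramp_ms} ms each) exceed burst duration "
                f"{self.duration_ms} ms"
            )
        if self.level_dbfs > 0:
            raise ValueError(f"level_dbfs must be <= 0, got {self.level_dbfs}")


def _pink_interior(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-peak pink noise: amplitude spectrum ~ 1/sqrt(f), random phases."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.size)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])
    return np.fft.irfft(spec, n=n)


def synth_pink_burst(spec: StimulusSpec | None = None) -> np.ndarray:
    """Synthesize one stereo burst; returns an (n_samples, 2) float array.

    Both channels are identical (diotic delivery).  Samples outside the
    burst support are exactly zero; the envelope uses raised-cosine ramps of
    ``ramp_ms`` and the peak is scaled to ``level_dbfs``.
    """
    spec = spec or StimulusSpec()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_ms * spec.audio_fs / 1000.0))
    x = _pink_interior(rng, n)

    n_ramp = int(round(spec.ramp_ms * spec.audio_fs / 1000.0))
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    x = x * env

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (10.0 ** (spec.level_dbfs / 20.0) / peak)
    return np.column_stack([x, x])


def write_wav(waveform: np.ndarray, audio_fs: float, path: str | Path) -> None:
    """Write a stereo waveform as standard 16-bit PCM WAV."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 2 or waveform.shape[1] != 2:
        raise ValueError("waveform must have shape (n_samples, 2)")
    if np.max(np.abs(waveform)) > 1.0 + 1e-12:
        raise ValueError("waveform exceeds full scale [-1, 1]")
    pcm = np.round(waveform * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(audio_fs), pcm)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 16-bit PCM WAV back to float in [-1, 1]."""
    fs, pcm = wavfile.read(str(path))
    return pcm.astype(float) / 32767.0, float(fs)
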