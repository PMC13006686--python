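"""Seeded synthetic anesthesia-like EEG with exact ground truth.

The generator emulates the propofol delta regime: a chain of alternating
negative/positive half-sine half-waves (so every wave has exact ground-truth
zero-crossings and extrema), frontally weighted across channels, on top of a
1/f^exponent background synthesized by spectral shaping of seeded white
noise.  It is not a biophysical model — there is no traveling-wave
propagation, no burst suppression, and no evoked response to sound; what it
provides is a signal whose delta-wave times, amplitudes, and spectral slope
are known exactly, so the online detector and every offline stage can be
scored against ground truth.

Nociceptive arousal is emulated as a multiplicative suppression of the delta
component inside a time window, matching the qualitative picture of
nociception transiently disrupting slow-wave dynamics without inventing a
quantitative nociception model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import CondAnnotation, Recording

__all__ = [
    "SynthConfig",
    "make_delta_eeg",
    "inject_arousal",
    "make_protocol_scenario",
    "write_ground_truth",
    "PROTOCOL_SCHEDULE",
]

#: Protocol block schedule: label -> duration in seconds, in order.
PROTOCOL_SCHEDULE = (
    ("in_phase", 180.0),
    ("pause", 20.0),
    ("anti_phase", 180.0),
    ("pause", 20.0),
    ("sham", 180.0),
    ("pre_pain", 60.0),
    ("pain", 30.0),
    ("post_pain", 300.0),
)


def _default_gradient(n: int) -> tuple[float, ...]:
    """Anterior-to-posterior amplitude decay, 1.0 frontal to 0.3 occipital."""
    if n == 1:
        return (1.0,)
    return tuple(np.linspace(1.0, 0.3, n))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic delta-EEG generator.

    Defaults describe a desk-scale propofol-like regime: 32 channels at
    500 Hz, delta waves of 0.25-1 Hz with 80 uV mean extremum amplitude
    (lognormal, CV 0.25), a frontal-to-occipital amplitude gradient, and a
    pink (1/f) background of 10 uV RMS.
    """

    n_channels: int = 32
    fs: float = 500.0
    duration_s: float = 60.0
    delta_freq_range: tuple[float, float] = (0.25, 1.0)
    delta_amp_mean_uv: float = 80.0
    delta_amp_cv: float = 0.25
    frontal_gradient: tuple[float, ...] | None = None
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        lo, hi = self.delta_freq_range
        if not (0.1 <= lo < hi <= 4.0):
            raise ValueError(
                f"delta_freq_range must satisfy 0.1 <= low < high <= 4, got {lo, hi}"
            )
        if self.delta_amp_mean_uv <= 0:
            raise ValueError(
                f"delta_amp_mean_uv must be > 0, got {self.delta_amp_mean_uv}"
            )
        if self.delta_amp_cv < 0:
            raise ValueError(f"delta_amp_cv must be >= 0, got {self.delta_amp_cv}")
        if self.noise_rms_uv < 0:
            raise ValueError(f"noise_rms_uv must be >= 0, got {self.noise_rms_uv}")
        if self.frontal_gradient is not None:
            grad = tuple(float(g) for g in self.frontal_gradient)
            if len(grad) != self.n_channels:
                raise ValueError(
                    f"frontal_gradient has {len(grad)} entries for "
                    f"{self.n_channels} channels"
                )
            if any(not 0 <= g <= 1 for g in grad):
                raise ValueError("frontal_gradient multipliers must lie in [0, 1]")
            object.__setattr__(self, "frontal_gradient", grad)

    @property
    def gradient(self) -> tuple[float, ...]:
        if self.frontal_gradient is not None:
            return self.frontal_gradient
        return _default_gradient(self.n_channels)


def _lognormal_amps(rng: np.random.Generator, n: int, mean: float, cv: float
                    ) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float
                ) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of seeded random phases."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _delta_chain(rng: np.random.Generator, config: SynthConfig
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate alternating negative/positive half-sine half-waves.

    Returns the 1-D delta trace (unit frontal gain) and the ground-truth
    wave table.  Each wave is a (negative, positive) half-wave pair; its
    half-periods are drawn uniformly so the wave frequency 1/d lies inside
    ``delta_freq_range``, and each half-wave's extremum amplitude is drawn
    lognormally.
    """
    fs = config.fs
    n_samples = int(round(config.duration_s * fs))
    lo, hi = config.delta_freq_range
    half_lo, half_hi = 1.0 / (2.0 * hi), 1.0 / (2.0 * lo)

    out = np.zeros(n_samples)
    rows = []
    t0 = 0.0
    while True:
        tau1, tau2 = rng.uniform(half_lo, half_hi, size=2)
        if (t0 + tau1 + tau2) * fs > n_samples:
            break
        a1, a2 = _lognormal_amps(rng, 2, config.delta_amp_mean_uv,
                                 config.delta_amp_cv)
        i0, i1 = int(np.ceil(t0 * fs)), int(np.ceil((t0 + tau1) * fs))
        i2 = int(np.ceil((t0 + tau1 + tau2) * fs))
        tt = np.arange(i0, i1) / fs
        out[i0:i1] = -a1 * np.sin(np.pi * (tt - t0) / tau1)
        tt = np.arange(i1, i2) / fs
        out[i1:i2] = a2 * np.sin(np.pi * (tt - t0 - tau1) / tau2)
        rows.append(
            dict(
                t_zc1_s=t0,
                t_e1_s=t0 + tau1 / 2.0,
                t_e2_s=t0 + tau1 + tau2 / 2.0,
                t_zc3_s=t0 + tau1 + tau2,
                v_e1_uv=-a1,
                v_e2_uv=a2,
            )
        )
        t0 += tau1 + tau2
    truth = pd.DataFrame(
        rows, columns=["t_zc1_s", "t_e1_s", "t_e2_s", "t_zc3_s",
                       "v_e1_uv", "v_e2_uv"]
    )
    return out, truth


def make_delta_eeg(config: SynthConfig) -> Recording:
    """Generate a seeded delta-dominant recording with known ground truth.

    The returned :class:`Recording` carries the pure delta component in
    ``delta_component`` and the generated wave table (one row per wave, with
    a ``channel`` column naming the frontal-most channel on which detection
    oracles operate) in ``ground_truth``.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.fs))
    delta_1d, truth = _delta_chain(rng, config)
    gradient = np.asarray(config.gradient)

    delta = gradient[:, None] * delta_1d[None, :]
    noise = np.empty((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        noise[ch] = _pink_noise(rng, n_samples, config.noise_exponent,
                                config.noise_rms_uv)

    labels = [f"ch{idx:03d}" for idx in range(config.n_channels)]
    truth = truth.assign(channel=labels[0])
    return Recording(
        data=delta + noise,
        fs=config.fs,
        channel_labels=labels,
        annotations=[],
        delta_component=delta,
        ground_truth=truth,
    )


def inject_arousal(
    recording: Recording,
    window: tuple[float, float],
    suppression: float,
    annotate: bool = True,
) -> Recording:
    """Suppress the delta component inside a window by a fixed fraction.

    The delta component (ground truth carried by the generator) is
    multiplied by ``1 - suppression`` inside ``window = (onset_s,
    duration_s)``; the background noise and everything outside the window
    are untouched.  With ``annotate=True`` a ``pain`` condition annotation
    marks the window.
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValueError(f"suppression must lie in [0, 1], got {suppression}")
    onset_s, duration_s = window
    if onset_s < 0 or onset_s + duration_s > recording.duration_s + 1e-9:
        raise ValueError(
            f"window {window} outside recording of {recording.duration_s} s"
        )
    if recording.delta_component is None:
        raise ValueError(
            "recording carries no delta_component ground truth to suppress"
        )
    out = recording.copy()
    if suppression > 0.0:
        i0 = int(round(onset_s * recording.fs))
        i1 = int(round((onset_s + duration_s) * recording.fs))
        removed = suppression * out.delta_component[:, i0:i1]
        out.data[:, i0:i1] -= removed
        out.delta_component[:, i0:i1] -= removed
    if annotate:
        out.annotations = sorted(
            out.annotations + [CondAnnotation("pain", onset_s, duration_s)],
            key=lambda a: a.onset_s,
        )
        out._check_annotations()
    return out


def make_protocol_scenario(
    config: SynthConfig, pain_suppression: float = 0.6
) -> Recording:
    """Generate the full stimulation-protocol scenario with annotations.

    Blocks, in order: in-phase 180 s, pause 20 s, anti-phase 180 s, pause
    20 s, sham 180 s, then pre-pain 60 s, pain 30 s (with delta suppression
    injected), post-pain 300 s.  ``config.duration_s`` is overridden by the
    schedule total (970 s).
    """
    from dataclasses import replace

    total = sum(d for _, d in PROTOCOL_SCHEDULE)
    config = replace(config, duration_s=total)
    rec = make_delta_eeg(config)

    anns = []
    t0 = 0.0
    pain_window = None
    for label, dur in PROTOCOL_SCHEDULE:
        anns.append(CondAnnotation(label, t0, dur))
        if label == "pain":
            pain_window = (t0, dur)
        t0 += dur
    rec.annotations = anns
    rec._check_annotations()
    # the pain annotation above already marks the window
    return inject_arousal(rec, pain_window, pain_suppression, annotate=False)


def write_ground_truth(recording: Recording, path) -> None:
    """Export the generator's wave table as TSV."""
    if recording.ground_truth is None:
        raise ValueError("recording carries no ground-truth wave table")
    cols = ["t_zc1_s", "t_e1_s", "t_e2_s", "t_zc3_s", "v_e1_uv", "v_e2_uv",
            "channel"]
    recording.ground_truth[cols].to_csv(path, sep="\t", index=False)
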