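"""Offline preprocessing and condition segmentation.

Mirrors the offline analysis front end: drop listed channels, zero-phase
band-pass (0.1-50 Hz by default), re-reference to the common average, then
cut the recording into its labelled condition segments.  Zero-phase
(forward-backward) filtering is deliberate: offline analyses must not
phase-shift delta timing, in contrast to the causal chain used online.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import signal as sps

from .recording import Recording

__all__ = ["PreprocessConfig", "preprocess", "segment_conditions"]

#: Condition labels that analysis segments are built for (pauses excluded).
ANALYSIS_CONDITIONS = ("in_phase", "anti_phase", "sham", "pre_pain", "pain",
                       "post_pain")


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = (0.1, 50.0)
    drop_channels: tuple[str, ...] = ()
    reference: str = "average"
    filter_order: int = 6

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.reference != "average":
            raise ValueError(f"only 'average' reference is supported, got "
                             f"{self.reference!r}")


def preprocess(recording: Recording, config: PreprocessConfig | None = None
               ) -> Recording:
    """Drop channels, zero-phase band-pass, and average-reference."""
    config = config or PreprocessConfig()
    lo, hi = config.band
    if hi >= recording.fs / 2:
        raise ValueError(
            f"band upper edge {hi} Hz must be below Nyquist "
            f"({recording.fs / 2} Hz)"
        )
    keep = [i for i, lab in enumerate(recording.channel_labels)
            if lab not in config.drop_channels]
    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 channels remain after dropping "
            f"{config.drop_channels}"
        )
    data = recording.data[keep]
    labels = [recording.channel_labels[i] for i in keep]

    sos = sps.butter(config.filter_order, (lo, hi), btype="bandpass",
                     fs=recording.fs, output="sos")
    padlen = min(data.shape[1] - 1, int(10 * recording.fs))
    data = sps.sosfiltfilt(sos, data, axis=1, padlen=padlen)
    data = data - data.mean(axis=0, keepdims=True)  # common average reference

    return Recording(
        data=data,
        fs=recording.fs,
        channel_labels=labels,
        annotations=list(recording.annotations),
    )


def segment_conditions(recording: Recording) -> dict[str, Recording]:
    """Cut the recording into one sub-recording per condition label.

    Pauses are excluded.  Missing expected conditions produce a warning and
    are simply absent from the result.  Segments use half-open sample
    intervals, so concatenated segments never overlap or fabricate samples.
    """
    if not recording.annotations:
        raise ValueError("recording has no condition annotations")
    out: dict[str, Recording] = {}
    for ann in recording.annotations:
        if ann.label == "pause":
            continue
        i0 = int(round(ann.onset_s * recording.fs))
        i1 = int(round((ann.onset_s + ann.duration_s) * recording.fs))
        i1 = min(i1, recording.n_samples)
        seg = Recording(
            data=recording.data[:, i0:i1].copy(),
            fs=recording.fs,
            channel_labels=list(recording.channel_labels),
        )
        if ann.label in out:
            warnings.warn(
                f"multiple {ann.label!r} annotations; keeping the first",
                stacklevel=2,
            )
            continue
        out[ann.label] = seg
    missing = [lab for lab in ANALYSIS_CONDITIONS if lab not in out]
    if missing:
        warnings.warn(f"conditions absent from recording: {missing}",
                      stacklevel=2)
    return out
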