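"""Core in-memory containers shared by every stage of the toolkit.

A :class:`Recording` is the common currency: a channels x samples matrix in
microvolts with its sampling rate, channel labels, and a list of labelled
condition intervals (:class:`CondAnnotation`).  All times are in seconds and
sample indexing is 0-based throughout the package; condition intervals are
half-open, ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Condition labels understood by the protocol scenario and the segmenter.
CONDITION_LABELS = (
    "in_phase",
    "anti_phase",
    "sham",
    "pause",
    "pre_pain",
    "pain",
    "post_pain",
)


@dataclass(frozen=True)
class CondAnnotation:
    """One labelled condition interval of a recording."""

    label: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"label must be one of {CONDITION_LABELS}, got {self.label!r}"
            )
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    """Multichannel EEG segment in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per row of ``data``.
    annotations
        Non-overlapping labelled condition intervals.
    delta_component
        Optional ground-truth delta-wave component of ``data`` (same shape),
        carried by the synthetic generator so that later stages can manipulate
        or score the oscillatory part in isolation.  ``None`` for real data.
    ground_truth
        Optional table of generated delta waves (see ``synth.make_delta_eeg``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[CondAnnotation] = field(default_factory=list)
    delta_component: np.ndarray | None = None
    ground_truth: "object | None" = None  # pandas.DataFrame when present

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self._check_annotations()

    def _check_annotations(self) -> None:
        anns = sorted(self.annotations, key=lambda a: a.onset_s)
        for a in anns:
            if a.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation {a.label!r} ends at {a.end_s} s, beyond "
                    f"recording end {self.duration_s} s"
                )
        for prev, cur in zip(anns, anns[1:]):
            if cur.onset_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"annotations {prev.label!r} and {cur.label!r} overlap"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D trace of a single channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in {self.channel_labels}") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        rec = replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            annotations=list(self.annotations),
        )
        if self.delta_component is not None:
            rec.delta_component = self.delta_component.copy()
        return rec
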