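"""Offline delta-wave segmentation, morphology metrics, band power, and
evoked-response sham subtraction.

A delta wave is delimited by three consecutive zero-crossings of the
delta-filtered trace: a downward crossing, an upward crossing, and the next
downward crossing, enclosing a negative then a positive half-wave with one
extremum each.  Morphology follows the house formulas:

    amplitude   A = |V_e1 - V_e2|                 (peak-to-peak, uV)
    frequency   F = 1 / d                         (d = wave duration, s)
    slopes      |V_e1| / t_e1,  A / |t_e1 - t_e2|,  |V_e2| / (d - t_e2)
    transition  F_trans = 1 / (2 |t_e2 - t_e1|)
    density     N_waves / T                       (waves per second)

with t_e1, t_e2 measured relative to the first zero-crossing.  Zero-crossing
times are linearly interpolated between samples; extrema are taken at the
sample-level extremum.  The default retention gate keeps events of 0.25-10 s;
no amplitude gate is applied by default (the 75 uV swing criterion belongs to
the online detector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "DeltaWaveEvent",
    "WaveMetrics",
    "DEFAULT_BANDS",
    "segment_delta_waves",
    "wave_metrics",
    "events_table",
    "density",
    "band_power",
    "erp_difference",
    "roi_aggregate",
]

#: Canonical topography bands (Hz).  Connectivity uses its own band table.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class DeltaWaveEvent:
    """One segmented delta wave (times in seconds from recording start)."""

    t_zc1_s: float
    t_e1_s: float
    t_e2_s: float
    t_zc3_s: float
    v_e1_uv: float
    v_e2_uv: float
    channel: str = ""

    def __post_init__(self) -> None:
        if not self.t_zc1_s < self.t_e1_s < self.t_e2_s < self.t_zc3_s:
            raise ValueError(
                "event times must be ordered zc1 < e1 < e2 < zc3, got "
                f"{(self.t_zc1_s, self.t_e1_s, self.t_e2_s, self.t_zc3_s)}"
            )
        if self.v_e1_uv * self.v_e2_uv >= 0:
            raise ValueError(
                f"extrema must have opposite signs, got "
                f"{(self.v_e1_uv, self.v_e2_uv)}"
            )

    @property
    def d_s(self) -> float:
        """Wave duration: time between first and last zero-crossings."""
        return self.t_zc3_s - self.t_zc1_s


@dataclass(frozen=True)
class WaveMetrics:
    amplitude_uv: float
    frequency_hz: float
    slope_zc_e1: float
    slope_e1_e2: float
    slope_e2_zc: float
    f_trans_hz: float


def _crossings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated downward and upward zero-crossing times (in samples).

    A transition onto an exact zero (signal touches zero and stays, as at
    the boundary of an isolated wave embedded in silence) counts as a
    crossing at the zero sample.
    """
    a, b = x[:-1], x[1:]
    down = np.flatnonzero(((a >= 0) & (b < 0)) | ((a > 0) & (b == 0)))
    up = np.flatnonzero(((a < 0) & (b >= 0)) | ((a == 0) & (b > 0)))
    t_down = down + np.where(b[down] == 0, 1.0,
                             a[down] / (a[down] - b[down]))
    t_up = up + np.where(a[up] == 0, 0.0, -a[up] / (b[up] - a[up]))
    return t_down, t_up


def segment_delta_waves(
    signal: np.ndarray,
    fs: float,
    duration_gate: tuple[float, float] = (0.25, 10.0),
    min_amplitude_uv: float | None = None,
    band: tuple[float, float] | None = (0.1, 4.0),
    channel: str = "",
) -> list[DeltaWaveEvent]:
    """Segment a single channel into delta-wave events.

    ``band`` is the zero-phase filter applied before zero-crossing
    detection; pass ``None`` if the input is already delta-band limited.
    Candidates run downward crossing -> upward crossing -> next downward
    crossing (negative half-wave first); candidates outside the duration
    gate (inclusive) or, when given, below the peak-to-peak amplitude gate
    are dropped.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D (single channel)")
    if x.size < 3 or np.ptp(x) == 0:
        return []
    if band is not None:
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        padlen = min(x.size - 1, int(20 * fs))
        x = sps.sosfiltfilt(sos, x, padlen=padlen)

    t_down, t_up = _crossings(x)
    if t_down.size < 2 or t_up.size == 0:
        return []

    lo_d, hi_d = duration_gate
    eps = 0.5 / fs  # half-sample guard on the inclusive duration gate
    events: list[DeltaWaveEvent] = []
    up_idx = 0
    for k in range(t_down.size - 1):
        zc1, zc3 = t_down[k], t_down[k + 1]
        while up_idx < t_up.size and t_up[up_idx] <= zc1:
            up_idx += 1
        if up_idx >= t_up.size or t_up[up_idx] >= zc3:
            continue
        zc2 = t_up[up_idx]
        neg = np.arange(int(np.ceil(zc1)), int(np.floor(zc2)) + 1)
        pos = np.arange(int(np.ceil(zc2)), int(np.floor(zc3)) + 1)
        neg = neg[(x[neg] < 0)] if neg.size else neg
        pos = pos[(x[pos] > 0)] if pos.size else pos
        if neg.size == 0 or pos.size == 0:
            continue
        i_e1 = neg[np.argmin(x[neg])]
        i_e2 = pos[np.argmax(x[pos])]
        d = (zc3 - zc1) / fs
        if not (lo_d - eps <= d <= hi_d + eps):
            continue
        v1, v2 = float(x[i_e1]), float(x[i_e2])
        if min_amplitude_uv is not None and abs(v1 - v2) < min_amplitude_uv:
            continue
        if not zc1 < i_e1 < i_e2 < zc3:
            continue
        events.append(
            DeltaWaveEvent(
                t_zc1_s=zc1 / fs,
                t_e1_s=i_e1 / fs,
                t_e2_s=i_e2 / fs,
                t_zc3_s=zc3 / fs,
                v_e1_uv=v1,
                v_e2_uv=v2,
                channel=channel,
            )
        )
    return events


def wave_metrics(event: DeltaWaveEvent) -> WaveMetrics:
    """Morphology metrics of one wave, computed exactly per the formulas."""
    te1 = event.t_e1_s - event.t_zc1_s
    te2 = event.t_e2_s - event.t_zc1_s
    d = event.d_s
    if te1 == te2:
        raise ValueError("degenerate event: extrema coincide in time")
    amplitude = abs(event.v_e1_uv - event.v_e2_uv)
    return WaveMetrics(
        amplitude_uv=amplitude,
        frequency_hz=1.0 / d,
        slope_zc_e1=abs(event.v_e1_uv) / te1,
        slope_e1_e2=amplitude / abs(te1 - te2),
        slope_e2_zc=abs(event.v_e2_uv) / (d - te2),
        f_trans_hz=1.0 / (2.0 * abs(te2 - te1)),
    )


def events_table(events: list[DeltaWaveEvent]) -> pd.DataFrame:
    """One row per event with its morphology metrics appended."""
    rows = []
    for ev in events:
        m = wave_metrics(ev)
        rows.append(
            dict(
                channel=ev.channel,
                t_zc1_s=ev.t_zc1_s,
                t_e1_s=ev.t_e1_s,
                t_e2_s=ev.t_e2_s,
                t_zc3_s=ev.t_zc3_s,
                v_e1_uv=ev.v_e1_uv,
                v_e2_uv=ev.v_e2_uv,
                d_s=ev.d_s,
                amplitude_uv=m.amplitude_uv,
                frequency_hz=m.frequency_hz,
                slope_zc_e1=m.slope_zc_e1,
                slope_e1_e2=m.slope_e1_e2,
                slope_e2_zc=m.slope_e2_zc,
                f_trans_hz=m.f_trans_hz,
            )
        )
    return pd.DataFrame(rows)


def density(events: list, total_duration_s: float) -> float:
    """Delta-wave density: events per second over the full duration."""
    if total_duration_s <= 0:
        raise ValueError(f"total_duration_s must be > 0, got {total_duration_s}")
    return len(events) / total_duration_s


def band_power(
    recording: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Welch band power per channel (uV^2), integrated over each band.

    Bands whose low edge cannot be resolved with at least two cycles in the
    segment are reported absent with a warning.
    """
    bands = bands or DEFAULT_BANDS
    n = recording.n_samples
    fs = recording.fs
    usable = {}
    for name, (lo, hi) in bands.items():
        if n / fs < 2.0 / lo:
            warnings.warn(
                f"segment too short for band {name!r} (needs >= {2.0 / lo:.0f} s)",
                stacklevel=2,
            )
            continue
        usable[name] = (lo, hi)
    nperseg = min(n, int(round(20.0 * fs)))
    freqs, psd = sps.welch(recording.data, fs=fs, nperseg=nperseg, axis=1)
    out = {}
    for name, (lo, hi) in usable.items():
        mask = (freqs >= lo) & (freqs <= hi)
        out[name] = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    return pd.DataFrame(out, index=recording.channel_labels)


def _epochs(
    data: np.ndarray, fs: float, sample_indices: list[int],
    window: tuple[float, float],
) -> tuple[np.ndarray, int]:
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    kept, dropped = [], 0
    for s in sample_indices:
        a, b = s + i0, s + i1
        if a < 0 or b > data.shape[1]:
            dropped += 1
            continue
        kept.append(data[:, a:b])
    if not kept:
        return np.empty((0,)), dropped
    return np.stack(kept), dropped


def erp_difference(
    recording: Recording,
    stim_events: list,
    sham_events: list,
    window: tuple[float, float] = (-0.5, 1.0),
    baseline: bool = False,
) -> tuple[np.ndarray, dict]:
    """Stimulus-locked average minus virtual-sham-locked average.

    ``stim_events`` / ``sham_events`` are trigger events (anything with a
    ``sample_index`` attribute) or plain sample indices.  Epochs exceeding
    the recording bounds are dropped and counted.  With ``baseline=True``
    the pre-onset mean of each epoch is subtracted first.  Returns the
    per-channel difference waveform ``(n_channels, n_times)`` and an info
    dict with epoch counts and the epoch time axis.
    """
    def _indices(events: list) -> list[int]:
        return [getattr(ev, "sample_index", ev) for ev in events]

    stim, n_drop_stim = _epochs(recording.data, recording.fs,
                                _indices(stim_events), window)
    sham, n_drop_sham = _epochs(recording.data, recording.fs,
                                _indices(sham_events), window)
    if stim.size == 0 or sham.size == 0:
        raise ValueError("no usable epochs fully inside the recording")
    if baseline:
        n_pre = max(1, int(round(-window[0] * recording.fs)))
        stim = stim - stim[:, :, :n_pre].mean(axis=2, keepdims=True)
        sham = sham - sham[:, :, :n_pre].mean(axis=2, keepdims=True)
    diff = stim.mean(axis=0) - sham.mean(axis=0)
    times = (np.arange(diff.shape[1]) + int(round(window[0] * recording.fs))
             ) / recording.fs
    info = dict(
        n_stim=stim.shape[0],
        n_sham=sham.shape[0],
        n_dropped_stim=n_drop_stim,
        n_dropped_sham=n_drop_sham,
        times_s=times,
    )
    return diff, info


def roi_aggregate(
    per_channel_table: pd.DataFrame, roi_map: dict[str, str]
) -> pd.DataFrame:
    """Average a per-channel table into regions of interest.

    ``roi_map`` maps channel label -> ROI name (each channel to at most one
    ROI).  Unmapped channels are ignored; their count is attached as
    ``result.attrs['n_unmapped']``.  ROIs with no member channels in the
    table are absent with a warning.
    """
    rois: dict[str, list[str]] = {}
    unmapped = 0
    for ch in per_channel_table.index:
        roi = roi_map.get(ch)
        if roi is None:
            unmapped += 1
        else:
            rois.setdefault(roi, []).append(ch)
    empty = set(roi_map.values()) - set(rois)
    if empty:
        warnings.warn(f"ROIs with no member channels: {sorted(empty)}",
                      stacklevel=2)
    out = pd.DataFrame(
        {roi: per_channel_table.loc[chs].mean(axis=0) for roi, chs in
         rois.items()}
    ).T
    out.attrs["n_unmapped"] = unmapped
    return out
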