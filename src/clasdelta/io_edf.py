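"""EDF (European Data Format) I/O for recordings.

Writing produces EDF+C: 16-bit samples, one-second data records, per-channel
physical scaling in microvolts, and condition annotations encoded as a
standard time-stamped annotation (TAL) signal.  Reading goes through MNE's
EDF reader, which also serves as an independent check of the writer.

EDF stores an integer number of fixed-duration records; recordings whose
length is not a whole number of seconds are zero-padded to the next full
second on write (the padding reads back as trailing zeros).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .recording import CONDITION_LABELS, CondAnnotation, Recording

__all__ = ["read_edf", "write_edf"]


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF header field too long: {text!r} (> {width})")
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width EDF header field."""
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def _annotation_records(annotations: list[CondAnnotation], n_records: int,
                        record_dur: float) -> list[bytes]:
    """Build one TAL byte string per record; events all go in record 0."""
    tals = []
    for rec in range(n_records):
        tal = f"+{rec * record_dur:g}\x14\x14\x00".encode("ascii")
        if rec == 0:
            for ann in annotations:
                tal += (
                    f"+{ann.onset_s:g}\x15{ann.duration_s:g}\x14"
                    f"{ann.label}\x14\x00"
                ).encode("ascii")
        tals.append(tal)
    return tals


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF+C with its condition annotations."""
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_records = math.ceil(recording.n_samples / spr)
    data = recording.data
    if n_records * spr != recording.n_samples:
        pad = n_records * spr - recording.n_samples
        data = np.pad(data, ((0, 0), (0, pad)))

    n_sig = recording.n_channels
    tals = _annotation_records(recording.annotations, n_records, 1.0)
    ann_spr = max(8, math.ceil(max(len(t) for t in tals) / 2))

    # physical scaling: symmetric per-channel range
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.0001, 1e-6)
    dig_max = 32767

    header_bytes = 256 * (1 + n_sig + 1)
    head = b""
    head += _field("0", 8)
    head += _field("X X X X", 80)                      # local patient id
    head += _field("Startdate 01-JAN-2000 X X X", 80)  # local recording id
    head += _field("01.01.00", 8)
    head += _field("00.00.00", 8)
    head += _num(header_bytes, 8)
    head += _field("EDF+C", 44)
    head += _num(n_records, 8)
    head += _num(1.0, 8)
    head += _num(n_sig + 1, 4)

    labels = [lab[:16] for lab in recording.channel_labels]
    sig_fields = [
        (labels + ["EDF Annotations"], 16),
        ([""] * n_sig + [""], 80),                     # transducer
        (["uV"] * n_sig + [""], 8),                    # physical dimension
        ([f"{-m:.7g}"[:8] for m in phys_max] + ["-1"], 8),
        ([f"{m:.7g}"[:8] for m in phys_max] + ["1"], 8),
        ([str(-dig_max)] * n_sig + ["-32768"], 8),
        ([str(dig_max)] * n_sig + ["32767"], 8),
        ([""] * n_sig + [""], 80),                     # prefiltering
        ([str(spr)] * n_sig + [str(ann_spr)], 8),
        ([""] * n_sig + [""], 32),                     # reserved
    ]
    for values, width in sig_fields:
        for v in values:
            head += _field(v, width)

    scale = dig_max / phys_max
    with open(path, "wb") as fh:
        fh.write(head)
        for rec in range(n_records):
            block = data[:, rec * spr:(rec + 1) * spr]
            digital = np.round(block * scale[:, None]).astype("<i2")
            fh.write(digital.tobytes())
            tal = tals[rec].ljust(ann_spr * 2, b"\x00")
            fh.write(tal)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in microvolts).

    Annotations whose description matches a known condition label are mapped
    to :class:`CondAnnotation`; others are ignored.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"unreadable EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE scales uV-dimensioned channels to V
    annotations = [
        CondAnnotation(desc, float(onset), float(dur))
        for desc, onset, dur in zip(
            raw.annotations.description, raw.annotations.onset,
            raw.annotations.duration
        )
        if desc in CONDITION_LABELS
    ]
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=annotations,
    )
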