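"""File formats: EDF recordings, CSV annotation/probability tables, WAV audio.

EDF reading goes through :mod:`mne`. Writing uses a minimal EDF implementation
(version "0" header, 16-bit samples, 1 s data records, integer sampling
rates): the physical range defaults to ±500 μV, giving a quantization step of
1000/65535 ≈ 0.0153 μV, far below EEG noise.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import AnnotationTrack, EEGRecording

__all__ = [
    "write_edf",
    "read_edf",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_probabilities_csv",
    "read_probabilities_csv",
    "write_wav",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        b = b[:n]
    return b.ljust(n)


def write_edf(
    path,
    rec: EEGRecording,
    physical_range_uv: tuple[float, float] = (-500.0, 500.0),
) -> None:
    """Write a recording as 16-bit EDF.

    Requires an integer sampling rate; data is truncated to whole 1 s records
    and clipped to ``physical_range_uv``.
    """
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s EDF data record")
    pmin, pmax = physical_range_uv
    ns = rec.n_channels

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_pad(lbl, 16) for lbl in rec.channel_labels),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad("uV", 8) for _ in range(ns)),
            b"".join(_pad(f"{pmin:g}", 8) for _ in range(ns)),
            b"".join(_pad(f"{pmax:g}", 8) for _ in range(ns)),
            b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad(str(fs), 8) for _ in range(ns)),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )

    x = np.clip(rec.data[:, : n_records * fs], pmin, pmax)
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    dig = np.rint((x - pmin) * gain + _DIG_MIN).astype("<i2")
    # EDF interleaves per data record: record 0 [ch0 fs samples, ch1 ...], ...
    interleaved = dig.reshape(ns, n_records, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        interleaved.tofile(fh)


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (μV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(
        data=data_uv,
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_labels=[str(c) for c in raw.ch_names],
    )


def write_annotations_csv(path, ann: AnnotationTrack) -> None:
    df = pd.DataFrame(ann.events, columns=["onset_s", "offset_s"])
    df.to_csv(path, index=False)


def read_annotations_csv(path) -> AnnotationTrack:
    df = pd.read_csv(path)
    return AnnotationTrack([(r.onset_s, r.offset_s) for r in df.itertuples()])


def write_probabilities_csv(path, trace) -> None:
    """Persist a ProbabilityTrace as time_s, <channel columns>, fused."""
    cols = {"time_s": trace.times_s}
    for i, lbl in enumerate(trace.channel_labels):
        cols[lbl] = trace.per_channel[i]
    cols["fused"] = trace.fused
    pd.DataFrame(cols).to_csv(path, index=False)


def read_probabilities_csv(path):
    from .detector import ProbabilityTrace

    df = pd.read_csv(path)
    labels = [c for c in df.columns if c not in ("time_s", "fused")]
    return ProbabilityTrace(
        per_channel=df[labels].to_numpy().T,
        fused=df["fused"].to_numpy(),
        times_s=df["time_s"].to_numpy(),
        channel_labels=labels,
    )


def write_wav(path, samples: np.ndarray, rate_hz: int) -> None:
    """Write float samples in [-1, 1] as PCM16 WAV (frames x channels)."""
    clipped = np.clip(samples, -1.0, 1.0)
    pcm = np.rint(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(Path(path)), int(rate_hz), pcm)
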