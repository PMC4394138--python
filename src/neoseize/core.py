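"""Core containers shared across the pipeline: recordings and annotations.

An :class:`EEGRecording` is a channels x samples matrix in microvolts with a
sampling rate and unique channel labels — the object every processing stage
consumes and produces. An :class:`AnnotationTrack` is an ordered list of
half-open seizure intervals ``[onset, offset)`` in seconds; expert ground
truth and detector output share this shape so they can be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEGRecording",
    "AnnotationTrack",
    "merge_intervals",
    "total_overlap",
    "total_duration",
]


@dataclass
class EEGRecording:
    """Multi-channel EEG signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sample_rate_hz : float
        Sampling rate, > 0.
    channel_labels : list of str
        Unique channel names (e.g. referential ``"F4"`` or bipolar ``"F4-C4"``).
    start_time_s : float
        Time of the first sample, seconds.
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the signal of one channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present in recording") from None
        return self.data[idx]

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), channel_labels=list(self.channel_labels))


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping half-open seizure intervals in seconds."""

    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b)) for a, b in self.events]
        for onset, offset in self.events:
            if not onset < offset:
                raise ValueError(f"event ({onset}, {offset}) has onset >= offset")
        for (a0, b0), (a1, _) in zip(self.events, self.events[1:]):
            if a1 < b0:
                raise ValueError("events must be sorted and non-overlapping")
            if a1 < a0:
                raise ValueError("events must be sorted by onset")

    @classmethod
    def from_events(cls, events) -> "AnnotationTrack":
        """Build a track from possibly unsorted intervals (overlaps merged)."""
        return cls(merge_intervals(events))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def total_s(self) -> float:
        return total_duration(self.events)


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Sort half-open intervals and merge any that touch or overlap."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged: list[tuple[float, float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def total_duration(intervals) -> float:
    """Total length covered by non-overlapping intervals."""
    return float(sum(b - a for a, b in intervals))


def total_overlap(a, b) -> float:
    """Total length of the intersection of two interval lists (each sorted,
    non-overlapping)."""
    out = 0.0
    j = 0
    b = list(b)
    for a0, a1 in a:
        while j < len(b) and b[j][1] <= a0:
            j += 1
        k = j
        while k < len(b) and b[k][0] < a1:
            out += max(0.0, min(a1, b[k][1]) - max(a0, b[k][0]))
            k += 1
    return float(out)
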