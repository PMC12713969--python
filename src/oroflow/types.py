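"""Core domain containers shared across the pipeline.

A :class:`Recording` is one device's set of signals (here: an oral or
nasal pressure channel plus the accelerometry-derived "activity" channel),
each with its own native sampling rate. An :class:`EventList` holds
manually scored (or simulated ground-truth) mouth-breathing intervals
expressed in seconds relative to one device's recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Channel", "Recording", "Event", "EventList", "merge_intervals"]


@dataclass
class Channel:
    """One signal: samples in physical units and the sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("channel samples must be a 1-D array")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.samples) < self.fs:
            raise ValidationError(
                f"channel must cover at least 1 s: {len(self.samples)} samples at {self.fs} Hz"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Recording:
    """One device's multichannel signal set.

    ``channels`` is keyed by signal role ("oral", "nasal", "activity").
    ``start_time`` is an absolute timestamp in seconds (POSIX, fractional
    allowed); it is informational — inter-device alignment never trusts the
    device clocks and is always estimated from the shared activity signals.
    """

    device_id: str
    channels: dict[str, Channel]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")

    @property
    def duration(self) -> float:
        """Recording duration in seconds (shortest channel governs)."""
        return min(ch.duration for ch in self.channels.values())

    def channel(self, role: str) -> Channel:
        from .errors import ChannelNotFoundError

        try:
            return self.channels[role]
        except KeyError:
            raise ChannelNotFoundError(role, role, self.channels.keys()) from None


@dataclass(frozen=True)
class Event:
    """One scored interval: onset and duration in seconds, plus its label."""

    onset: float
    duration: float
    label: str = "mouth_breathing"

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EventList:
    """Scored events on a single device's timeline, sorted by onset.

    Overlapping events are permitted; consumers that need disjoint cover
    call :func:`merge_intervals` first.
    """

    events: list[Event] = field(default_factory=list)
    timeline_ref: str = ""

    def __post_init__(self) -> None:
        for ev in self.events:
            if not ev.duration > 0:
                raise ValidationError(f"event duration must be positive, got {ev}")
        self.events = sorted(self.events, key=lambda e: (e.onset, e.duration))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def merged_intervals(self) -> list[tuple[float, float]]:
        """Interval union of all events as (start, end) pairs."""
        return merge_intervals([(e.onset, e.end) for e in self.events])


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals; output sorted and pairwise disjoint."""
    out: list[list[float]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
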