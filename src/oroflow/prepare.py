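"""Per-recording preparation: sync -> filter -> trim -> normalize -> segment -> label.

This is the chain every recording pair passes through before windows
reach the classifier, for training and for validation alike. Majority
down-sampling is *not* part of this chain — it applies only to training
corpora, never to evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import FilterSpec, NASAL_FILTER, ORAL_FILTER, lowpass, normalize
from .segmentation import (
    DEFAULT_EVENT_FRACTION,
    DEFAULT_STRIDE_S,
    DEFAULT_WINDOW_S,
    SegmentSet,
    label_segments,
    make_segments,
)
from .sync import DEFAULT_MAX_LAG, align_and_trim, estimate_lag_recordings, shift_events
from .types import EventList, Recording

__all__ = ["PipelineParams", "prepare_recording_pair"]


@dataclass
class PipelineParams:
    """Everything the preparation chain needs, with pipeline defaults.

    ``event_timeline`` names the device the annotation onsets are relative
    to: "a" (the nasal device, the reference timeline) or "b" (the oral
    device, whose onsets must be shifted by the estimated lag).
    """

    oral_filter: FilterSpec = field(default_factory=lambda: ORAL_FILTER)
    nasal_filter: FilterSpec = field(default_factory=lambda: NASAL_FILTER)
    window_s: float = DEFAULT_WINDOW_S
    stride_s: float = DEFAULT_STRIDE_S
    event_fraction: float = DEFAULT_EVENT_FRACTION
    max_lag: float = DEFAULT_MAX_LAG
    target_fs: float | None = None
    event_timeline: str = "a"


def prepare_recording_pair(
    rec_a: Recording,
    rec_b: Recording,
    events: EventList,
    params: PipelineParams | None = None,
    lag: float | None = None,
) -> SegmentSet:
    """Run one device pair through the preparation chain.

    Device A carries the nasal channel, device B the oral channel. The
    inter-device lag is estimated from the activity channels unless given
    explicitly. Returns labeled windows on the common timeline.
    """
    params = params or PipelineParams()
    if lag is None:
        lag = estimate_lag_recordings(rec_a, rec_b, max_lag=params.max_lag)
    pair = align_and_trim(rec_a, rec_b, lag, target_fs=params.target_fs)
    oral = normalize(lowpass(pair.oral, pair.fs, params.oral_filter))
    nasal = normalize(lowpass(pair.nasal, pair.fs, params.nasal_filter))
    interval = (pair.t0, pair.t0 + pair.common_duration)
    shift = lag if params.event_timeline == "b" else 0.0
    common_events = shift_events(events, shift, interval=interval)
    segments = make_segments(
        oral,
        nasal,
        pair.fs,
        window_s=params.window_s,
        stride_s=params.stride_s,
        subject_id=rec_a.device_id,
    )
    return label_segments(segments, common_events, event_fraction=params.event_fraction)
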