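"""oroflow: mouth-breathing event detection from dual-device PSG pressure signals.

The package turns a pair of EDF recordings — a nasal-pressure device and
an oral-pressure device with independent clocks — into segment-level
mouth-breathing detections: cross-correlation clock alignment on the
shared movement channels, Butterworth low-pass filtering, per-recording
normalization, overlapping 10 s windowing with coverage-based labels,
class rebalancing, and a dual-input 1-D CNN classifier, plus a synthetic
generator so the whole chain is testable without clinical data.
"""

__version__ = "0.1.0"

from .errors import OroflowError
from .types import Channel, Event, EventList, Recording
from .preprocess import FilterSpec, lowpass, normalize
from .sync import AlignedPair, align_and_trim, estimate_lag, estimate_lag_recordings, shift_events
from .segmentation import (
    SegmentSet,
    downsample_majority,
    label_segments,
    make_segments,
    split_train_test,
)
from .model import (
    DualInputCNN,
    MetricsReport,
    ModelConfig,
    build_model,
    compute_metrics,
    predict,
    secondary_validate,
    train,
)
from .prepare import PipelineParams, prepare_recording_pair
from .synthgen import SimParams, make_params, simulate_subject, simulate_window_bank
from .pipeline import run_pipeline

__all__ = [
    "__version__",
    "OroflowError",
    "Channel",
    "Event",
    "EventList",
    "Recording",
    "FilterSpec",
    "lowpass",
    "normalize",
    "AlignedPair",
    "align_and_trim",
    "estimate_lag",
    "estimate_lag_recordings",
    "shift_events",
    "SegmentSet",
    "make_segments",
    "label_segments",
    "downsample_majority",
    "split_train_test",
    "DualInputCNN",
    "ModelConfig",
    "MetricsReport",
    "build_model",
    "train",
    "predict",
    "compute_metrics",
    "secondary_validate",
    "PipelineParams",
    "prepare_recording_pair",
    "SimParams",
    "make_params",
    "simulate_subject",
    "simulate_window_bank",
    "run_pipeline",
]
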