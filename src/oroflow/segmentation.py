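"""Windowing, labeling, rebalancing and splitting.

The aligned, filtered, normalized signal pair is cut into 10 s windows
advanced by 5 s. A window is labeled a mouth-breathing event ([1, 0]) when
at least half of it is covered by scored mouth breathing — concurrent
nasal flow does not matter — and a non-event ([0, 1]) otherwise. Because
events are rare over a full night, the non-event class is down-sampled
(default: to 2% of its original size) before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import StratificationError, ValidationError
from .types import EventList, merge_intervals

__all__ = [
    "SegmentSet",
    "make_segments",
    "label_segments",
    "downsample_majority",
    "split_train_test",
]

EVENT = np.array([1, 0], dtype=np.int64)
NON_EVENT = np.array([0, 1], dtype=np.int64)

DEFAULT_WINDOW_S = 10.0
DEFAULT_STRIDE_S = 5.0
DEFAULT_EVENT_FRACTION = 0.5
DEFAULT_KEEP_FRACTION = 0.02
DEFAULT_TEST_FRACTION = 0.33


@dataclass
class SegmentSet:
    """Parallel arrays of fixed-length oral/nasal windows.

    ``targets`` rows are one-hot: [1, 0] = event, [0, 1] = non-event;
    unlabeled sets have an empty ``targets`` array. ``start_times`` are
    window starts in seconds on the common timeline.
    """

    oral: np.ndarray
    nasal: np.ndarray
    targets: np.ndarray
    subject_ids: np.ndarray
    start_times: np.ndarray
    fs: float
    window_s: float = DEFAULT_WINDOW_S
    stride_s: float = DEFAULT_STRIDE_S

    def __post_init__(self) -> None:
        if self.oral.shape != self.nasal.shape:
            raise ValidationError("oral and nasal window arrays must be congruent")
        if len(self.targets) and len(self.targets) != len(self.oral):
            raise ValidationError("targets length does not match window count")

    def __len__(self) -> int:
        return len(self.oral)

    @property
    def labeled(self) -> bool:
        return len(self.targets) == len(self.oral) and len(self.oral) > 0

    @property
    def is_event(self) -> np.ndarray:
        return self.targets[:, 0] == 1

    @property
    def n_events(self) -> int:
        return int(self.is_event.sum()) if self.labeled else 0

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            oral=self.oral[idx],
            nasal=self.nasal[idx],
            targets=self.targets[idx] if len(self.targets) else self.targets,
            subject_ids=self.subject_ids[idx],
            start_times=self.start_times[idx],
            fs=self.fs,
            window_s=self.window_s,
            stride_s=self.stride_s,
        )

    @staticmethod
    def concatenate(sets: list["SegmentSet"]) -> "SegmentSet":
        first = sets[0]
        for s in sets[1:]:
            if (s.fs, s.window_s, s.stride_s) != (first.fs, first.window_s, first.stride_s):
                raise ValidationError("cannot concatenate segment sets with differing geometry")
        return SegmentSet(
            oral=np.concatenate([s.oral for s in sets]),
            nasal=np.concatenate([s.nasal for s in sets]),
            targets=np.concatenate([s.targets for s in sets])
            if all(len(s.targets) for s in sets)
            else np.empty((0, 2), dtype=np.int64),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            start_times=np.concatenate([s.start_times for s in sets]),
            fs=first.fs,
            window_s=first.window_s,
            stride_s=first.stride_s,
        )

    # -- serialization ------------------------------------------------------

    def save(self, path) -> Path:
        """One file with named arrays plus a JSON sidecar manifest."""
        import json

        path = Path(path)
        np.savez_compressed(
            path,
            oral=self.oral,
            nasal=self.nasal,
            targets=self.targets,
            subject_ids=self.subject_ids.astype(str),
            start_times=self.start_times,
        )
        path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        sidecar = {
            "fs": self.fs,
            "window_s": self.window_s,
            "stride_s": self.stride_s,
            "n_windows": int(len(self)),
            "n_events": int(self.n_events) if self.labeled else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @staticmethod
    def load(path) -> "SegmentSet":
        import json

        path = Path(path)
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        return SegmentSet(
            oral=arrays["oral"],
            nasal=arrays["nasal"],
            targets=arrays["targets"],
            subject_ids=arrays["subject_ids"],
            start_times=arrays["start_times"],
            fs=meta["fs"],
            window_s=meta["window_s"],
            stride_s=meta["stride_s"],
        )


def make_segments(
    oral: np.ndarray,
    nasal: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float = DEFAULT_STRIDE_S,
    subject_id: str = "",
) -> SegmentSet:
    """Cut the signal pair into windows starting at 0, stride, 2*stride, ...

    Only windows lying fully inside the signal are emitted; the window
    count obeys ``floor((T - W) / S) + 1`` for T >= W and is 0 otherwise.
    """
    oral = np.asarray(oral, dtype=np.float64)
    nasal = np.asarray(nasal, dtype=np.float64)
    if oral.shape != nasal.shape or oral.ndim != 1:
        raise ValidationError("oral and nasal signals must be 1-D arrays of equal length")
    if stride_s <= 0 or window_s <= 0:
        raise ValidationError("window_s and stride_s must be positive")
    w = int(round(window_s * fs))
    s = stride_s * fs
    n_total = len(oral)
    starts: list[int] = []
    k = 0
    while True:
        i0 = int(round(k * s))
        if i0 + w > n_total:
            break
        starts.append(i0)
        k += 1
    idx = np.array(starts, dtype=np.int64)
    if len(idx):
        gather = idx[:, None] + np.arange(w)[None, :]
        ow, nw = oral[gather], nasal[gather]
    else:
        ow = np.empty((0, w))
        nw = np.empty((0, w))
    return SegmentSet(
        oral=ow,
        nasal=nw,
        targets=np.empty((0, 2), dtype=np.int64),
        subject_ids=np.array([subject_id] * len(idx), dtype=object),
        start_times=idx / fs,
        fs=fs,
        window_s=window_s,
        stride_s=stride_s,
    )


def _overlap_seconds(start: float, end: float, intervals: list[tuple[float, float]]) -> float:
    total = 0.0
    for s, e in intervals:
        total += max(0.0, min(end, e) - max(start, s))
    return total


def label_segments(
    segments: SegmentSet,
    events: EventList,
    event_fraction: float = DEFAULT_EVENT_FRACTION,
) -> SegmentSet:
    """Assign one-hot targets by the coverage rule.

    A window is an event iff the union of scored intervals covers at least
    ``event_fraction`` of it (inclusive, so exactly 50% counts). Events
    must already be on the segments' timeline; overlaps are merged first
    because "contains mouth breathing" is a property of time covered, not
    of event count.
    """
    if not 0.0 <= event_fraction <= 1.0:
        raise ValidationError("event_fraction must lie in [0, 1]")
    merged = events.merged_intervals()
    targets = np.empty((len(segments), 2), dtype=np.int64)
    for i, t0 in enumerate(segments.start_times):
        cover = _overlap_seconds(float(t0), float(t0) + segments.window_s, merged)
        targets[i] = EVENT if cover / segments.window_s >= event_fraction else NON_EVENT
    out = segments.subset(np.arange(len(segments)))
    out.targets = targets
    return out


def downsample_majority(
    segments: SegmentSet,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    seed: int = 0,
) -> SegmentSet:
    """Down-sample the non-event class; all event windows are kept.

    ``round(keep_fraction * N_nonevent)`` non-events are drawn uniformly
    without replacement and the output order is randomized. Deterministic
    given ``seed``.
    """
    import logging

    if not 0.0 < keep_fraction <= 1.0:
        raise ValidationError("keep_fraction must lie in (0, 1]")
    if not segments.labeled:
        raise ValidationError("segments must be labeled before rebalancing")
    rng = np.random.default_rng(seed)
    ev_idx = np.flatnonzero(segments.is_event)
    ne_idx = np.flatnonzero(~segments.is_event)
    if len(ne_idx) == 0:
        logging.getLogger(__name__).warning(
            "downsample_majority: no non-event windows; returning input unchanged"
        )
        return segments
    n_keep = int(np.rint(keep_fraction * len(ne_idx)))
    kept_ne = rng.choice(ne_idx, size=n_keep, replace=False)
    idx = np.concatenate([ev_idx, kept_ne])
    return segments.subset(rng.permutation(idx))


def split_train_test(
    segments: SegmentSet,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> tuple[SegmentSet, SegmentSet]:
    """Stratified random partition into train and test sets.

    ``|test| = round(test_fraction * n)`` with the class mix of the test
    set within one window of the input mix; both halves keep at least one
    window of each class present in the input.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie in (0, 1)")
    n = len(segments)
    if n < 3:
        raise ValidationError("need at least 3 windows to split")
    if not segments.labeled:
        raise ValidationError("segments must be labeled before splitting")
    rng = np.random.default_rng(seed)
    ev_idx = np.flatnonzero(segments.is_event)
    ne_idx = np.flatnonzero(~segments.is_event)
    for name, cls in (("event", ev_idx), ("non-event", ne_idx)):
        if 0 < len(cls) < 2:
            raise StratificationError(
                f"class {name!r} has {len(cls)} window(s); need >= 2 to stratify"
            )
    n_test = int(np.rint(test_fraction * n))
    n_test_ev = int(np.rint(test_fraction * len(ev_idx))) if len(ev_idx) else 0
    n_test_ne = n_test - n_test_ev
    # both halves must keep >= 1 window of every class that exists
    if len(ev_idx):
        n_test_ev = min(max(n_test_ev, 1), len(ev_idx) - 1)
    n_test_ne = min(max(n_test_ne, 1 if len(ne_idx) else 0), max(len(ne_idx) - 1, 0))
    ev_perm = rng.permutation(ev_idx)
    ne_perm = rng.permutation(ne_idx)
    test_idx = np.concatenate([ev_perm[:n_test_ev], ne_perm[:n_test_ne]])
    train_idx = np.concatenate([ev_perm[n_test_ev:], ne_perm[n_test_ne:]])
    return segments.subset(rng.permutation(train_idx)), segments.subset(
        rng.permutation(test_idx)
    )
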