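"""Two-device time alignment.

The two recorders free-run on independent clocks, so their timelines are
offset by an unknown constant. Both devices carry an accelerometry-derived
"activity" channel that sees the same body movements; the offset is
estimated as the argmax of the normalized cross-correlation of the
mean-removed activity signals over integer sample lags. The recordings are
then cropped to their common time interval.

Sign convention: a positive lag means device B started *later* than
device A, i.e. ``b(t) ~ a(t + lag)`` when both are indexed by their own
local time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, EmptyOverlapError, ValidationError
from .types import Event, EventList, Recording

__all__ = [
    "AlignedPair",
    "estimate_lag",
    "estimate_lag_recordings",
    "align_and_trim",
    "shift_events",
]

#: sampling rate activity signals are decimated to before correlation —
#: body movement is low-frequency, so 10 Hz keeps the peak and cuts cost
CORRELATION_FS = 10.0

DEFAULT_MAX_LAG = 60.0


@dataclass
class AlignedPair:
    """Oral and nasal channels cropped to the same absolute time interval.

    ``t0`` is where the common interval starts on device A's timeline;
    window start times downstream are relative to this origin.
    """

    oral: np.ndarray
    nasal: np.ndarray
    fs: float
    lag_applied: float
    common_duration: float
    t0: float = 0.0


def estimate_lag(
    activity_a: np.ndarray,
    activity_b: np.ndarray,
    fs: float,
    max_lag: float = DEFAULT_MAX_LAG,
) -> float:
    """Clock offset of device B relative to device A, in seconds.

    Argmax over integer-sample lags in ``[-max_lag, +max_lag]`` of the
    normalized cross-correlation of the mean-removed signals. Ties are
    broken toward the smallest ``|lag|``. Sub-sample refinement is not
    attempted: one sample at the correlation rate is two orders of
    magnitude below the 10 s analysis window.
    """
    a = np.asarray(activity_a, dtype=np.float64)
    b = np.asarray(activity_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("activity signals must be 1-D arrays")
    if len(a) < 10 * fs or len(b) < 10 * fs:
        raise ValidationError("activity signals must be at least 10 s long")
    if max_lag > min(len(a), len(b)) / fs / 2:
        raise ValidationError(
            f"max_lag {max_lag} s exceeds half the shorter signal's duration"
        )
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        raise DegenerateSignalError("activity signal has zero variance")
    a /= sa
    b /= sb

    # full cross-correlation; index k corresponds to lag (k - (len(b)-1)) samples
    # of a relative to b, i.e. positive lag = b delayed = b starts later
    cc = sps.correlate(a, b, mode="full", method="auto")
    lags = np.arange(-(len(b) - 1), len(a))
    max_lag_samples = int(np.floor(max_lag * fs))
    keep = np.abs(lags) <= max_lag_samples
    cc, lags = cc[keep], lags[keep]
    # tie-break: highest correlation, then smallest |lag|, then negative first
    order = np.lexsort((lags, np.abs(lags), -cc))
    return float(lags[order[0]] / fs)


def _resample_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if fs == target_fs:
        return np.asarray(x, dtype=np.float64)
    ratio = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=np.float64), ratio.numerator, ratio.denominator)


def estimate_lag_recordings(
    rec_a: Recording,
    rec_b: Recording,
    max_lag: float = DEFAULT_MAX_LAG,
    corr_fs: float = CORRELATION_FS,
) -> float:
    """Estimate the clock offset from the recordings' activity channels.

    Both activity channels are decimated to ``corr_fs`` before correlation
    (anti-aliased polyphase resampling).
    """
    a = rec_a.channel("activity")
    b = rec_b.channel("activity")
    da = _resample_to(a.samples, a.fs, corr_fs)
    db = _resample_to(b.samples, b.fs, corr_fs)
    return estimate_lag(da, db, corr_fs, max_lag=max_lag)


def align_and_trim(
    rec_a: Recording,
    rec_b: Recording,
    lag: float,
    role_a: str = "nasal",
    role_b: str = "oral",
    target_fs: float | None = None,
) -> AlignedPair:
    """Crop both pressure channels to the common absolute time interval.

    Device A carries the nasal channel and device B the oral channel by
    default (roles configurable). If the two rates differ, the higher-rate
    channel is decimated to the common rate (the lower of the two unless
    ``target_fs`` overrides it). On device A's timeline, A spans
    ``[0, dur_a]`` and B spans ``[lag, lag + dur_b]``.
    """
    cha = rec_a.channel(role_a)
    chb = rec_b.channel(role_b)
    if abs(lag) >= min(cha.duration, chb.duration):
        raise EmptyOverlapError(
            f"|lag| = {abs(lag)} s is not smaller than the shortest recording"
        )
    fs = target_fs if target_fs is not None else min(cha.fs, chb.fs)
    xa = _resample_to(cha.samples, cha.fs, fs)
    xb = _resample_to(chb.samples, chb.fs, fs)

    t0 = max(0.0, lag)
    t1 = min(len(xa) / fs, lag + len(xb) / fs)
    if t1 <= t0:
        raise EmptyOverlapError(f"no overlap: interval [{t0}, {t1}] is empty")
    n = int(np.floor((t1 - t0) * fs))
    ia = int(np.round(t0 * fs))
    ib = int(np.round((t0 - lag) * fs))
    nasal = xa[ia : ia + n] if role_a == "nasal" else xb[ib : ib + n]
    oral = xb[ib : ib + n] if role_b == "oral" else xa[ia : ia + n]
    n = min(len(nasal), len(oral))
    return AlignedPair(
        oral=oral[:n],
        nasal=nasal[:n],
        fs=fs,
        lag_applied=lag,
        common_duration=n / fs,
        t0=t0,
    )


def shift_events(
    events: EventList,
    lag: float,
    interval: tuple[float, float] | None = None,
) -> EventList:
    """Translate event onsets by ``lag`` seconds, optionally clipping.

    With ``interval=(start, end)``, events wholly outside are dropped and
    partially-outside events are clipped; onsets are then re-expressed
    relative to ``start`` (the common-timeline origin).
    """
    out: list[Event] = []
    for ev in events:
        s, e = ev.onset + lag, ev.end + lag
        if interval is not None:
            lo, hi = interval
            s2, e2 = max(s, lo), min(e, hi)
            if e2 <= s2:
                continue
            out.append(Event(onset=s2 - lo, duration=e2 - s2, label=ev.label))
        else:
            out.append(Event(onset=s, duration=ev.duration, label=ev.label))
    return EventList(events=out, timeline_ref=events.timeline_ref)
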