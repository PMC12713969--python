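"""Reading and writing the formats the pipeline touches.

Signals travel as EDF (European Data Format) files, one per recording
device; scored mouth-breathing events travel as a three-column table
(``onset,duration,label``) in CSV or XLSX.

EDF reading is delegated to :func:`mne.io.read_raw_edf`; each channel is
read individually so that it keeps its native sampling rate (a shared
container would resample mixed-rate channels to a common grid). Writing
uses a minimal EDF encoder: 16-bit samples, one-second data records, the
physical range taken from the signal with headroom. Digital values are
computed from the header-encoded (ASCII-rounded) physical range so that a
round trip is exact up to one quantization step of
``(physical_max - physical_min) / 65535``.
"""

from __future__ import annotations

import logging
import math
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, FormatError, ValidationError
from .types import Channel, Event, EventList, Recording

__all__ = ["read_recording", "write_recording", "read_events", "write_events"]

logger = logging.getLogger(__name__)

DEFAULT_EVENT_LABEL = "mouth_breathing"

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


# ---------------------------------------------------------------------------
# EDF writing
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _format_physical(x: float) -> str:
    """Render a physical bound into <= 8 ASCII characters."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValidationError(f"cannot encode physical bound {x} in 8 characters")


def _record_duration(rates: list[float]) -> Fraction:
    """Smallest record duration (in s) making every samples-per-record integral."""
    for denom in (1, 2, 4, 5, 10):
        dur = Fraction(denom, 1) if denom == 1 else Fraction(denom)
        # try durations 1, 2, 4, 5, 10 seconds
        if all(float(fs) * denom == int(round(fs * denom)) and fs * denom >= 1 for fs in rates):
            if all(abs(fs * denom - round(fs * denom)) < 1e-9 for fs in rates):
                return Fraction(denom)
    raise ValidationError(
        f"sampling rates {rates} are not expressible with an integral "
        "number of samples per EDF record (tried record durations 1-10 s)"
    )


def write_recording(recording: Recording, path) -> Path:
    """Write ``recording`` to ``path`` as a plain EDF file.

    The signal is truncated to a whole number of data records; physical
    min/max are set from the observed signal range with 5% headroom (a
    constant signal gets a +/-1 band so the scale is well defined).
    """
    path = Path(path)
    roles = list(recording.channels.keys())
    rates = [recording.channels[r].fs for r in roles]
    rec_dur = _record_duration(rates)
    spr = [int(round(fs * rec_dur)) for fs in rates]  # samples per record
    n_records = min(
        int(len(recording.channels[r].samples) // s) for r, s in zip(roles, spr)
    )
    if n_records < 1:
        raise ValidationError("recording shorter than one EDF data record")

    start = datetime.fromtimestamp(recording.start_time, tz=timezone.utc)
    n_sig = len(roles)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field(f"Startdate X X X X dev_{recording.device_id}"[:80], 80),
            _ascii_field(start.strftime("%d.%m.%y"), 8),
            _ascii_field(start.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (1 + n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(
                int(rec_dur) if rec_dur.denominator == 1 else float(rec_dur), 8
            ),
            _ascii_field(n_sig, 4),
        ]
    )

    phys_lo: list[float] = []
    phys_hi: list[float] = []
    for r in roles:
        x = recording.channels[r].samples
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            lo, hi = lo - 1.0, hi + 1.0
        else:
            pad = 0.05 * (hi - lo)
            lo, hi = lo - pad, hi + pad
        # re-parse the ASCII form so writer and reader agree on the scale
        lo_s, hi_s = _format_physical(lo), _format_physical(hi)
        phys_lo.append(float(lo_s))
        phys_hi.append(float(hi_s))

    def sig_fields(fmt) -> bytes:
        return b"".join(fmt(i) for i in range(n_sig))

    header += sig_fields(lambda i: _ascii_field(roles[i][:16], 16))
    header += sig_fields(lambda i: _ascii_field("", 80))          # transducer
    header += sig_fields(lambda i: _ascii_field("a.u.", 8))       # physical dim
    header += sig_fields(lambda i: _ascii_field(_format_physical(phys_lo[i]), 8))
    header += sig_fields(lambda i: _ascii_field(_format_physical(phys_hi[i]), 8))
    header += sig_fields(lambda i: _ascii_field(_EDF_DIG_MIN, 8))
    header += sig_fields(lambda i: _ascii_field(_EDF_DIG_MAX, 8))
    header += sig_fields(lambda i: _ascii_field("", 80))          # prefiltering
    header += sig_fields(lambda i: _ascii_field(spr[i], 8))
    header += sig_fields(lambda i: _ascii_field("", 32))

    digital: list[np.ndarray] = []
    for i, r in enumerate(roles):
        x = recording.channels[r].samples[: n_records * spr[i]]
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_hi[i] - phys_lo[i])
        d = np.rint((x - phys_lo[i]) * scale + _EDF_DIG_MIN)
        digital.append(np.clip(d, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for i in range(n_sig):
                fh.write(digital[i][rec * spr[i] : (rec + 1) * spr[i]].tobytes())
    return path


# ---------------------------------------------------------------------------
# EDF reading (MNE-backed)
# ---------------------------------------------------------------------------

def _edf_channel_names(path: Path) -> list[str]:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # mne raises assorted errors on corrupt headers
        raise FormatError(f"cannot parse EDF header of {path}: {exc}") from exc
    return list(raw.ch_names)


def read_recording(path, channel_map: dict[str, str], device_id: str | None = None) -> Recording:
    """Read the channels named in ``channel_map`` (role -> EDF label).

    Each channel is loaded at its native sampling rate and in the file's
    physical units. Roles are the pipeline's names: "oral", "nasal",
    "activity" (any subset).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    available = _edf_channel_names(path)
    channels: dict[str, Channel] = {}
    start_time = 0.0
    for role, name in channel_map.items():
        if name not in available:
            raise ChannelNotFoundError(role, name, available)
        raw = mne.io.read_raw_edf(
            path, include=[name], preload=True, verbose="error", units="a.u."
        )
        data = raw.get_data(units=None)[0]
        channels[role] = Channel(np.asarray(data, dtype=np.float64), float(raw.info["sfreq"]))
        meas = raw.info["meas_date"]
        if meas is not None:
            start_time = meas.timestamp()
    return Recording(
        device_id=device_id or path.stem,
        channels=channels,
        start_time=start_time,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("onset", "duration", "label")


def read_events(
    path,
    event_label: str = DEFAULT_EVENT_LABEL,
    timeline_ref: str = "",
) -> EventList:
    """Read scored events from a CSV or XLSX table.

    Rows whose ``label`` equals ``event_label`` (case-insensitively) are
    returned sorted by onset; other rows are ignored with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"event table {path} is missing required column {col!r}")

    events: list[Event] = []
    n_ignored = 0
    for idx, row in df.iterrows():
        label = str(row["label"]).strip()
        if label.lower() != event_label.lower():
            n_ignored += 1
            continue
        onset, duration = float(row["onset"]), float(row["duration"])
        if duration <= 0:
            raise ValidationError(
                f"event table {path} row {idx}: duration must be positive, got {duration}"
            )
        if math.isnan(onset) or math.isnan(duration):
            raise ValidationError(f"event table {path} row {idx}: non-finite value")
        events.append(Event(onset=onset, duration=duration, label=label))
    if n_ignored:
        logger.info("read_events(%s): ignored %d rows with other labels", path, n_ignored)
    return EventList(events=events, timeline_ref=timeline_ref)


def write_events(events: EventList, path) -> Path:
    """Write an event table in the canonical CSV schema."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset": [e.onset for e in events],
            "duration": [e.duration for e in events],
            "label": [e.label for e in events],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path
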