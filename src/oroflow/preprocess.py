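"""Low-pass filtering and normalization of the pressure signals.

Both pressure channels are low-pass filtered with a 6th-order Butterworth
filter — oral at 2 Hz, nasal at 1.5 Hz — to strip sensor noise while
keeping the breathing waveform (breathing sits well below 1 Hz; its useful
harmonics below ~2 Hz). The filter is applied forward-backward by default
(zero phase), so events stay aligned with their annotations; a causal mode
is available for streaming parity. Signals are then z-scored over the
whole recording (population convention), preserving *relative* amplitude
differences between segments — the cue that separates real breathing from
the muted noise floor of the unused channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, ValidationError

__all__ = ["FilterSpec", "lowpass", "normalize", "ORAL_FILTER", "NASAL_FILTER"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters.

    ``order`` is the order of the designed filter; in zero-phase mode the
    effective magnitude response is squared (the classic filtfilt
    convention), which only sharpens the roll-off.
    """

    order: int = 6
    cutoff: float = 2.0
    family: str = "butterworth"
    phase: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValidationError(f"filter order must be even and >= 2, got {self.order}")
        if not self.cutoff > 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")
        if self.family != "butterworth":
            raise ValidationError(f"unsupported filter family {self.family!r}")
        if self.phase not in ("zero_phase", "causal"):
            raise ValidationError(f"phase must be 'zero_phase' or 'causal', got {self.phase!r}")


ORAL_FILTER = FilterSpec(order=6, cutoff=2.0)
NASAL_FILTER = FilterSpec(order=6, cutoff=1.5)


def lowpass(x: np.ndarray, fs: float, spec: FilterSpec = ORAL_FILTER) -> np.ndarray:
    """Apply the low-pass filter; output has the same length as the input.

    Zero-phase mode reflects the signal at both ends for filter warm-up so
    edge transients do not contaminate the first and last windows.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("lowpass expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    if spec.cutoff >= fs / 2:
        raise ValidationError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    if len(x) < 3 * spec.order:
        raise ValidationError(
            f"signal too short to filter: {len(x)} samples < {3 * spec.order}"
        )
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.phase == "zero_phase":
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def normalize(x: np.ndarray) -> np.ndarray:
    """Z-score over the whole recording: mean 0, population SD 1."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("normalize expects a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSignalError("cannot normalize a zero-variance signal")
    return (x - np.mean(x)) / sd
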