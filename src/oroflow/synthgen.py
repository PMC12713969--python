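"""Synthetic two-device respiratory-pressure recordings with ground truth.

No clinical recordings ship with this package, so every stage is
exercised against a generator that emulates what the real measurement
setup produces: a nasal-pressure cannula on the main device and an
oral-pressure cannula on a second device whose clock is offset by an
unknown constant, plus a movement ("activity") channel on each device
that sees the same body movements.

The generated phenomenology covers the three archetypal window types —
quasi-periodic nasal breathing with the oral channel at the sensor noise
floor, mouth-only breathing with the nasal channel muted, and oronasal
mixtures with attenuated flow on both channels — along with movement
artifacts injected as simultaneous bursts into both devices (which is
precisely what makes cross-correlation synchronization solvable).

The breath waveform is a harmonic half-wave model (positive half-sine
inspiration with second/third harmonics, smaller negative half-sine
expiration, an end-expiratory pause, per-breath period jitter) rather
than recorded templates: it keeps the repository data-free and the
waveforms analytically checkable. Per-subject shape and amplitude
parameters can be drawn once per subject, which is what enables the
within-subject versus unseen-subject generalization experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import SchedulingError, ValidationError
from .segmentation import SegmentSet
from .types import Channel, Event, EventList, Recording

__all__ = [
    "SimParams",
    "GroundTruth",
    "PRESETS",
    "make_params",
    "schedule_episodes",
    "simulate_breath_train",
    "simulate_subject",
    "simulate_window_bank",
    "export_dataset",
]

#: per-sample breathing-route codes in :class:`GroundTruth`
MODE_NASAL, MODE_MOUTH, MODE_ORONASAL, MODE_ARTIFACT = 0, 1, 2, 3

_BASE_START_TIME = 1677708000.0  # an arbitrary fixed evening timestamp (UTC)


@dataclass
class SimParams:
    """Generator parameters; defaults are one plausible pediatric night.

    ``mouth_fraction`` is the expected fraction of time spent inside
    mouth-breathing episodes (a few percent of the night for a snoring
    child); ``oronasal_fraction`` is the share of those episodes that
    retain partial nasal flow. ``clock_offset`` is device B's start delay
    relative to device A (positive = B switched on later). Amplitudes are
    in arbitrary pressure units; ``noise_sd`` is the sensor noise floor
    on the same scale.
    """

    duration: float = 1800.0
    fs: float = 200.0
    activity_fs: float = 25.0
    breath_rate: float = 18.0
    breath_jitter: float = 0.15
    mouth_fraction: float = 0.04
    oronasal_fraction: float = 0.30
    episode_dur: tuple[float, float] = (8.0, 45.0)
    min_gap: float = 10.0
    artifact_rate: float = 20.0
    clock_offset: float = 4.0
    subject_amp: float = 1.0
    noise_sd: float = 0.03
    oronasal_split: float = 0.5
    subject_variability: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mouth_fraction < 1.0:
            raise ValidationError("mouth_fraction must lie in [0, 1)")
        if self.episode_dur[0] < 5.0:
            raise ValidationError(
                "minimum episode duration must be >= 5 s so every event can "
                "dominate at least one 10 s window"
            )
        if self.episode_dur[0] > self.episode_dur[1]:
            raise ValidationError("episode_dur must be (min, max) with min <= max")
        # highest harmonic used is 3x the breath frequency
        if self.fs < 4 * 3 * self.breath_rate / 60.0:
            raise ValidationError("fs must be at least 4x the highest breath harmonic")
        if self.duration < 10.0:
            raise ValidationError("duration must be at least 10 s")


PRESETS: dict[str, dict] = {
    # pure mouth-only vs nasal-only content, no artifacts, devices in sync
    "easy": dict(
        mouth_fraction=0.5,
        oronasal_fraction=0.0,
        artifact_rate=0.0,
        clock_offset=0.0,
        subject_variability=False,
    ),
    # the standard study conditions
    "default": dict(subject_variability=True),
    # denser artifacts, noisier sensors, mostly mixed-route episodes
    "hard": dict(
        artifact_rate=60.0,
        noise_sd=0.08,
        oronasal_fraction=0.6,
        subject_variability=True,
    ),
}


def make_params(preset: str = "default", **overrides) -> SimParams:
    """Build :class:`SimParams` from a named preset plus overrides."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return SimParams(**kwargs)


@dataclass
class GroundTruth:
    """Simulator truth on device A's timeline.

    ``events`` is the annotation an infallible scorer would produce
    (mouth and oronasal episodes alike — all mouth breathing counts).
    ``mode_trace`` codes the breathing route per sample at ``fs``;
    artifact samples are marked only outside episodes so that the union
    of mouth+oronasal samples reconstructs the event list exactly.
    """

    events: EventList
    mode_trace: np.ndarray
    fs: float


@dataclass
class _SubjectShape:
    """Per-subject waveform idiosyncrasies (drawn once per subject)."""

    amp_oral: float = 1.0
    amp_nasal: float = 1.0
    breath_rate: float = 18.0
    h2: float = 0.25
    h3: float = 0.08
    insp_frac: float = 0.38
    exp_frac: float = 0.42
    exp_ratio: float = 0.8
    split: float = 0.5
    noise_scale: float = 1.0


def _draw_shape(params: SimParams, rng: np.random.Generator) -> _SubjectShape:
    if not params.subject_variability:
        return _SubjectShape(breath_rate=params.breath_rate, split=params.oronasal_split)
    return _SubjectShape(
        amp_oral=float(rng.lognormal(0.0, 0.25)),
        amp_nasal=float(rng.lognormal(0.0, 0.25)),
        breath_rate=float(rng.uniform(13.0, 22.0)),
        h2=float(rng.uniform(0.10, 0.35)),
        h3=float(rng.uniform(0.0, 0.15)),
        insp_frac=float(rng.uniform(0.33, 0.45)),
        exp_frac=float(rng.uniform(0.38, 0.46)),
        exp_ratio=float(rng.uniform(0.6, 0.95)),
        split=float(rng.uniform(0.35, 0.65)),
        noise_scale=float(rng.uniform(0.8, 1.3)),
    )


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


def _breath_train(
    n: int, fs: float, shape: _SubjectShape, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-periodic airflow-pressure waveform of length ``n`` samples."""
    out = np.zeros(n)
    t0 = 0.0
    period0 = 60.0 / shape.breath_rate
    while t0 * fs < n:
        period = period0 * (1.0 + rng.uniform(-jitter, jitter))
        i0 = int(round(t0 * fs))
        ni = int(round(shape.insp_frac * period * fs))
        ne = int(round(shape.exp_frac * period * fs))
        # inspiration: half-sine plus harmonics
        s = np.linspace(0.0, 1.0, ni, endpoint=False)
        insp = (
            np.sin(np.pi * s)
            + shape.h2 * np.sin(2 * np.pi * s)
            + shape.h3 * np.sin(3 * np.pi * s)
        )
        # expiration: smaller negative half-sine; rest of the period is pause
        s2 = np.linspace(0.0, 1.0, ne, endpoint=False)
        exp_ = -shape.exp_ratio * np.sin(np.pi * s2)
        seg = np.concatenate([insp, exp_])
        hi = min(i0 + len(seg), n)
        out[i0:hi] = seg[: hi - i0]
        t0 += period
    return out


def _smooth_gain(gate: np.ndarray, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    """Crossfade a 0/1 gate so route switches have no step discontinuity."""
    w = int(round(ramp_s * fs))
    if w < 2:
        return gate.astype(np.float64)
    kernel = np.hanning(w)
    kernel /= kernel.sum()
    padded = np.pad(gate.astype(np.float64), w, mode="edge")
    return np.convolve(padded, kernel, mode="same")[w:-w]


def simulate_breath_train(
    mode: str, duration: float, params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(oral, nasal) pressure traces for a single breathing route.

    ``mode`` is "nasal" (oral channel at the noise floor), "mouth" (nasal
    channel at the noise floor) or "oronasal" (both attenuated by the
    oronasal split). Output length is exactly ``duration * fs`` samples.
    """
    if mode not in ("nasal", "mouth", "oronasal"):
        raise ValidationError(f"unknown breathing mode {mode!r}")
    shape = _draw_shape(params, rng)
    n = int(round(duration * params.fs))
    train = _breath_train(n, params.fs, shape, params.breath_jitter, rng)
    gain_o, gain_n = {
        "nasal": (0.0, 1.0),
        "mouth": (1.0, 0.0),
        "oronasal": (shape.split, 1.0 - shape.split),
    }[mode]
    amp = params.subject_amp
    sd = params.noise_sd * shape.noise_scale
    oral = amp * shape.amp_oral * gain_o * train + rng.normal(0.0, sd, n)
    nasal = amp * shape.amp_nasal * gain_n * train + rng.normal(0.0, sd, n)
    return oral, nasal


# ---------------------------------------------------------------------------
# episode scheduling
# ---------------------------------------------------------------------------


def schedule_episodes(
    duration: float, params: SimParams, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Renewal schedule of (start, duration, kind) mouth/oronasal episodes.

    Episode lengths are uniform on ``episode_dur``; gaps are
    ``min_gap`` plus an exponential tail whose mean makes the expected
    covered fraction equal ``mouth_fraction``. Episodes never overlap and
    are separated by at least ``min_gap`` seconds.
    """
    mf = params.mouth_fraction
    if mf == 0.0:
        return []
    mean_ep = 0.5 * (params.episode_dur[0] + params.episode_dur[1])
    mean_gap = mean_ep * (1.0 - mf) / mf
    if mean_gap <= params.min_gap:
        raise SchedulingError(
            f"mouth_fraction {mf} requires a mean gap of {mean_gap:.1f} s, "
            f"below the required minimum gap of {params.min_gap} s"
        )
    episodes: list[tuple[float, float, str]] = []
    t = float(rng.exponential(mean_gap))
    while t + params.episode_dur[0] <= duration:
        dur = float(rng.uniform(*params.episode_dur))
        dur = min(dur, duration - t)  # still >= episode_dur[0] by the loop guard
        kind = "oronasal" if rng.random() < params.oronasal_fraction else "mouth"
        episodes.append((t, dur, kind))
        t += dur + params.min_gap + float(rng.exponential(mean_gap - params.min_gap))
    return episodes


# ---------------------------------------------------------------------------
# full subject
# ---------------------------------------------------------------------------


def simulate_subject(
    params: SimParams, subject_id: str | None = None
) -> tuple[Recording, Recording, GroundTruth]:
    """One subject's night: device A (nasal), device B (oral), ground truth.

    Both devices record the same physical scene; device B's sample clock
    starts ``clock_offset`` seconds after device A's. Shared movement
    bursts appear in both activity channels and as high-amplitude
    transients in both pressure channels.
    """
    rng = np.random.default_rng(params.seed)
    shape = _draw_shape(params, rng)
    sid = subject_id or f"S{params.seed:05d}"
    offset = params.clock_offset
    dur = params.duration

    # master timeline covering both devices' recording windows
    t_lo = min(0.0, offset)
    t_hi = max(dur, dur + offset)
    master_dur = t_hi - t_lo
    n = int(round(master_dur * params.fs))

    episodes = schedule_episodes(master_dur, params, rng)
    train = _breath_train(n, params.fs, shape, params.breath_jitter, rng)

    gate_o = np.zeros(n)
    gate_n = np.ones(n)
    mode_master = np.full(n, MODE_NASAL, dtype=np.uint8)
    for start, edur, kind in episodes:
        i0, i1 = int(round(start * params.fs)), int(round((start + edur) * params.fs))
        if kind == "mouth":
            gate_o[i0:i1] = 1.0
            gate_n[i0:i1] = 0.0
            mode_master[i0:i1] = MODE_MOUTH
        else:
            gate_o[i0:i1] = shape.split
            gate_n[i0:i1] = 1.0 - shape.split
            mode_master[i0:i1] = MODE_ORONASAL
    gain_o = _smooth_gain(gate_o, params.fs)
    gain_n = _smooth_gain(gate_n, params.fs)

    amp = params.subject_amp
    sd = params.noise_sd * shape.noise_scale
    oral = amp * shape.amp_oral * gain_o * train + rng.normal(0.0, sd, n)
    nasal = amp * shape.amp_nasal * gain_n * train + rng.normal(0.0, sd, n)

    # shared movement bursts: the sync anchor
    n_act = int(round(master_dur * params.activity_fs))
    act = rng.normal(0.0, 0.05, n_act)
    n_bursts = rng.poisson(params.artifact_rate * master_dur / 3600.0)
    burst_times = np.sort(rng.uniform(0.0, master_dur, n_bursts))
    for bt in burst_times:
        bdur = float(rng.uniform(1.0, 4.0))
        j0, j1 = int(round(bt * params.activity_fs)), int(round((bt + bdur) * params.activity_fs))
        j1 = min(j1, n_act)
        if j1 > j0:
            env = np.hanning(max(j1 - j0, 2))[: j1 - j0]
            act[j0:j1] += env * rng.normal(0.0, 1.0, j1 - j0)
        i0, i1 = int(round(bt * params.fs)), min(int(round((bt + bdur) * params.fs)), n)
        if i1 > i0:
            envp = np.hanning(max(i1 - i0, 2))[: i1 - i0]
            transient = envp * rng.normal(0.0, 5.0 * amp, i1 - i0)
            oral[i0:i1] += transient
            nasal[i0:i1] += transient
            outside = mode_master[i0:i1] == MODE_NASAL
            mode_master[i0:i1][outside] = MODE_ARTIFACT

    def _slice(x: np.ndarray, fs: float, t_start: float) -> np.ndarray:
        i0 = int(round((t_start - t_lo) * fs))
        return x[i0 : i0 + int(round(dur * fs))]

    rec_a = Recording(
        device_id=f"{sid}A",
        channels={
            "nasal": Channel(_slice(nasal, params.fs, 0.0), params.fs),
            "activity": Channel(_slice(act, params.activity_fs, 0.0), params.activity_fs),
        },
        start_time=_BASE_START_TIME,
    )
    rec_b = Recording(
        device_id=f"{sid}B",
        channels={
            "oral": Channel(_slice(oral, params.fs, offset), params.fs),
            "activity": Channel(_slice(act, params.activity_fs, offset), params.activity_fs),
        },
        start_time=_BASE_START_TIME + offset,
    )

    events = []
    for start, edur, kind in episodes:
        s = start + t_lo  # episode clock -> device A timeline
        e = min(s + edur, dur)
        s = max(s, 0.0)
        if e - s > 0:
            events.append(Event(onset=s, duration=e - s, label="mouth_breathing"))
    truth = GroundTruth(
        events=EventList(events=events, timeline_ref=rec_a.device_id),
        mode_trace=_slice(mode_master, params.fs, 0.0),
        fs=params.fs,
    )
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# pure-window bank (the "easy" training corpus)
# ---------------------------------------------------------------------------


def simulate_window_bank(
    n_windows: int,
    params: SimParams,
    seed: int | None = None,
    window_s: float = 10.0,
    filter_and_normalize: bool = True,
) -> SegmentSet:
    """Labeled windows that are each wholly one breathing route.

    Half the windows are mouth-only (events), half nasal-only
    (non-events), shuffled. Each window is synthesized independently,
    low-pass filtered with the pipeline's filters, and the bank is then
    z-scored per channel *globally* (the per-recording convention), so the
    amplitude contrast between active and muted channels survives — the
    cue the classifier and the energy oracle both rely on.
    """
    from .preprocess import NASAL_FILTER, ORAL_FILTER, lowpass

    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    w = int(round(window_s * params.fs))
    oral = np.empty((n_windows, w))
    nasal = np.empty((n_windows, w))
    targets = np.zeros((n_windows, 2), dtype=np.int64)
    modes = ["mouth" if i < n_windows // 2 else "nasal" for i in range(n_windows)]
    for i, mode in enumerate(modes):
        o, na = simulate_breath_train(mode, window_s, params, rng)
        if filter_and_normalize:
            o = lowpass(o, params.fs, ORAL_FILTER)
            na = lowpass(na, params.fs, NASAL_FILTER)
        oral[i], nasal[i] = o, na
        targets[i] = (1, 0) if mode == "mouth" else (0, 1)
    if filter_and_normalize:
        for arr in (oral, nasal):
            arr -= arr.mean()
            arr /= arr.std()
    perm = rng.permutation(n_windows)
    return SegmentSet(
        oral=oral[perm],
        nasal=nasal[perm],
        targets=targets[perm],
        subject_ids=np.array([f"bank{seed}"] * n_windows, dtype=object),
        start_times=np.arange(n_windows, dtype=np.float64) * window_s,
        fs=params.fs,
        window_s=window_s,
        stride_s=window_s,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_dataset(subjects: list[SimParams], out_dir) -> Path:
    """Write each subject as two EDF files plus an event CSV, with a manifest.

    Layout: ``sub###_a.edf`` (nasal device), ``sub###_b.edf`` (oral
    device), ``sub###_events.csv`` (ground-truth annotation on device A's
    timeline), and ``manifest.yaml`` recording every seed and parameter.
    """
    import yaml

    from .io import write_events, write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, params in enumerate(subjects):
        rec_a, rec_b, truth = simulate_subject(params, subject_id=f"sub{i:03d}")
        stem = f"sub{i:03d}"
        write_recording(rec_a, out_dir / f"{stem}_a.edf")
        write_recording(rec_b, out_dir / f"{stem}_b.edf")
        write_events(truth.events, out_dir / f"{stem}_events.csv")
        entry = {
            "subject": stem,
            "edf_a": f"{stem}_a.edf",
            "edf_b": f"{stem}_b.edf",
            "events": f"{stem}_events.csv",
            "params": asdict(params),
            "n_events": len(truth.events),
        }
        entry["params"]["episode_dur"] = list(params.episode_dur)
        entries.append(entry)
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump({"subjects": entries}, sort_keys=False))
    return manifest_path


def load_exported_subject(out_dir, stem: str) -> tuple[Recording, Recording, EventList]:
    """Reload one exported subject through the standard readers."""
    from .io import read_events, read_recording

    out_dir = Path(out_dir)
    rec_a = read_recording(
        out_dir / f"{stem}_a.edf", {"nasal": "nasal", "activity": "activity"},
        device_id=f"{stem}A",
    )
    rec_b = read_recording(
        out_dir / f"{stem}_b.edf", {"oral": "oral", "activity": "activity"},
        device_id=f"{stem}B",
    )
    events = read_events(out_dir / f"{stem}_events.csv", timeline_ref=f"{stem}A")
    return rec_a, rec_b, events
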