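"""Generator contracts: waveform statistics, scheduling, export round trips."""

import numpy as np
import pytest

from oroflow import make_params, simulate_subject
from oroflow.errors import SchedulingError, ValidationError
from oroflow.prepare import PipelineParams, prepare_recording_pair
from oroflow.sync import estimate_lag_recordings
from oroflow.synthgen import (
    MODE_MOUTH,
    MODE_ORONASAL,
    SimParams,
    export_dataset,
    load_exported_subject,
    schedule_episodes,
    simulate_breath_train,
)


class TestBreathTrain:
    params = SimParams(duration=60.0, fs=100.0, seed=0)

    def test_nasal_mode_channel_contrast(self):
        oral, nasal = simulate_breath_train("nasal", 60.0, self.params, np.random.default_rng(1))
        sd = self.params.noise_sd
        assert np.sqrt(np.mean(oral**2)) <= 3 * sd
        assert np.sqrt(np.mean(nasal**2)) >= 10 * sd

    def test_mouth_mode_mirrors(self):
        oral, nasal = simulate_breath_train("mouth", 60.0, self.params, np.random.default_rng(1))
        sd = self.params.noise_sd
        assert np.sqrt(np.mean(nasal**2)) <= 3 * sd
        assert np.sqrt(np.mean(oral**2)) >= 10 * sd

    def test_oronasal_mode_both_active(self):
        oral, nasal = simulate_breath_train("oronasal", 60.0, self.params, np.random.default_rng(1))
        sd = self.params.noise_sd
        assert np.sqrt(np.mean(oral**2)) >= 4 * sd
        assert np.sqrt(np.mean(nasal**2)) >= 4 * sd

    def test_exact_length(self):
        oral, nasal = simulate_breath_train("nasal", 12.34, self.params, np.random.default_rng(0))
        assert len(oral) == len(nasal) == int(round(12.34 * 100.0))

    def test_same_rng_state_identical(self):
        a, _ = simulate_breath_train("mouth", 20.0, self.params, np.random.default_rng(5))
        b, _ = simulate_breath_train("mouth", 20.0, self.params, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            simulate_breath_train("humming", 10.0, self.params, np.random.default_rng(0))

    def test_spectral_peak_near_breath_rate(self):
        params = SimParams(duration=120.0, fs=50.0, breath_rate=18.0, seed=0)
        _, nasal = simulate_breath_train("nasal", 120.0, params, np.random.default_rng(2))
        freqs = np.fft.rfftfreq(len(nasal), 1 / 50.0)
        spectrum = np.abs(np.fft.rfft(nasal))
        spectrum[freqs < 0.05] = 0.0  # ignore DC leakage
        peak = freqs[int(np.argmax(spectrum))]
        f0 = 18.0 / 60.0
        assert 0.8 * f0 <= peak <= 1.2 * f0


class TestScheduler:
    def test_monte_carlo_fraction(self):
        params = SimParams(duration=7200.0, mouth_fraction=0.2, seed=0)
        fracs = []
        for seed in range(50):
            eps = schedule_episodes(7200.0, params, np.random.default_rng(seed))
            fracs.append(sum(d for _, d, _ in eps) / 7200.0)
        assert abs(np.mean(fracs) - 0.2) <= 0.03

    def test_durations_and_gaps_respect_bounds(self):
        params = SimParams(duration=7200.0, mouth_fraction=0.3, seed=0)
        eps = schedule_episodes(7200.0, params, np.random.default_rng(1))
        assert len(eps) > 0
        for start, dur, _ in eps:
            assert dur >= params.episode_dur[0] - 1e-9
        for (s1, d1, _), (s2, _, _) in zip(eps, eps[1:]):
            assert s2 - (s1 + d1) >= params.min_gap - 1e-9

    def test_zero_fraction_empty(self):
        params = SimParams(duration=3600.0, mouth_fraction=0.0)
        assert schedule_episodes(3600.0, params, np.random.default_rng(0)) == []

    def test_unschedulable_fraction_rejected(self):
        params = SimParams(duration=3600.0, mouth_fraction=0.8)
        with pytest.raises(SchedulingError):
            schedule_episodes(3600.0, params, np.random.default_rng(0))


class TestSimulateSubject:
    def test_zero_fraction_pure_noise_oral(self):
        params = make_params(
            "default", duration=120.0, fs=50.0, mouth_fraction=0.0,
            artifact_rate=0.0, clock_offset=0.0, subject_variability=False, seed=3,
        )
        rec_a, rec_b, truth = simulate_subject(params)
        assert len(truth.events) == 0
        oral = rec_b.channels["oral"].samples
        assert np.sqrt(np.mean(oral**2)) <= 3 * params.noise_sd

    def test_clock_offset_recovered_by_sync(self, small_subject):
        rec_a, rec_b, _ = small_subject
        lag = estimate_lag_recordings(rec_a, rec_b)
        assert abs(lag - 4.0) <= 0.1  # one sample on the 10 Hz correlation grid

    def test_mode_trace_consistent_with_events(self, small_subject):
        _, _, truth = small_subject
        fs = truth.fs
        in_event = np.isin(truth.mode_trace, (MODE_MOUTH, MODE_ORONASAL))
        # reconstruct intervals from the per-sample trace
        rebuilt = []
        i = 0
        while i < len(truth.mode_trace):
            if in_event[i]:
                j = i
                while j < len(in_event) and in_event[j]:
                    j += 1
                rebuilt.append((i / fs, j / fs))
                i = j
            else:
                i += 1
        assert len(rebuilt) == len(truth.events)
        for (s, e), ev in zip(rebuilt, truth.events):
            assert s == pytest.approx(ev.onset, abs=1.5 / fs)
            assert e == pytest.approx(ev.end, abs=1.5 / fs)

    def test_event_durations_dominate_a_window(self, small_subject):
        _, _, truth = small_subject
        for ev in truth.events:
            assert ev.duration >= 5.0


class TestExport:
    def _params(self, seed, **kw):
        base = dict(
            duration=200.0, fs=50.0, mouth_fraction=0.2, oronasal_fraction=0.0,
            artifact_rate=30.0, clock_offset=3.3, subject_variability=False, seed=seed,
        )
        base.update(kw)
        return make_params("default", **base)

    def test_file_census(self, tmp_path):
        export_dataset([self._params(s) for s in range(3)], tmp_path)
        assert len(list(tmp_path.glob("*.edf"))) == 6
        assert len(list(tmp_path.glob("*_events.csv"))) == 3
        assert (tmp_path / "manifest.yaml").exists()

    def test_reexport_byte_identical_csvs(self, tmp_path):
        export_dataset([self._params(1)], tmp_path / "x")
        export_dataset([self._params(1)], tmp_path / "y")
        assert (tmp_path / "x" / "sub000_events.csv").read_bytes() == (
            tmp_path / "y" / "sub000_events.csv"
        ).read_bytes()

    def test_round_trip_label_agreement(self, tmp_path):
        """Exported EDF + CSV reloaded through the full chain reproduces truth."""
        params = self._params(7, artifact_rate=0.0)
        rec_a, rec_b, truth = __import__("oroflow").simulate_subject(
            params, subject_id="sub000"
        )
        export_dataset([params], tmp_path)
        ra, rb, events = load_exported_subject(tmp_path, "sub000")
        pp = PipelineParams()
        direct = prepare_recording_pair(rec_a, rec_b, truth.events, pp)
        reloaded = prepare_recording_pair(ra, rb, events, pp)
        assert len(direct) == len(reloaded)
        agree = np.mean(np.all(direct.targets == reloaded.targets, axis=1))
        assert agree >= 0.99
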