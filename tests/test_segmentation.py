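"""Window geometry, the coverage labeling rule, rebalancing and splitting."""

import numpy as np
import pytest

from oroflow import (
    Event,
    EventList,
    downsample_majority,
    label_segments,
    make_segments,
    split_train_test,
)
from oroflow.errors import StratificationError, ValidationError
from oroflow.segmentation import SegmentSet


def brute_force_window_count(T, W, S):
    """Enumerate window start times directly."""
    count, k = 0, 0
    while k * S + W <= T + 1e-9:
        count += 1
        k += 1
    return count


def _segments(T, fs=10.0, W=10.0, S=5.0):
    n = int(round(T * fs))
    return make_segments(np.zeros(n), np.zeros(n), fs, window_s=W, stride_s=S)


class TestMakeSegments:
    def test_sixty_second_signal_yields_eleven_windows(self):
        assert len(_segments(60.0)) == 11  # floor((60-10)/5)+1

    def test_exact_window_fits_once(self):
        assert len(_segments(10.0)) == 1

    def test_too_short_gives_empty(self):
        assert len(_segments(9.0)) == 0

    def test_count_formula_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            W = round(float(rng.uniform(2.0, 20.0)) * 2) / 2
            S = round(float(rng.uniform(0.5, 15.0)) * 2) / 2
            T = round(float(rng.uniform(W, 200.0)) * 2) / 2
            segs = _segments(T, fs=2.0, W=W, S=S)
            assert len(segs) == brute_force_window_count(T, W, S)
            assert len(segs) == int(np.floor((T - W) / S + 1e-9)) + 1

    def test_start_times_on_stride_grid(self):
        segs = _segments(60.0)
        assert np.allclose(segs.start_times, np.arange(11) * 5.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            make_segments(np.zeros(100), np.zeros(99), 10.0)


class TestLabeling:
    def _one_window(self):
        return _segments(10.0, fs=100.0)

    def _labels(self, events, fraction=0.5):
        segs = label_segments(self._one_window(), EventList(events), fraction)
        return segs.targets[0].tolist()

    def test_full_overlap_is_event(self):
        assert self._labels([Event(0, 10)]) == [1, 0]

    def test_half_coverage_inclusive(self):
        assert self._labels([Event(3.0, 5.0)]) == [1, 0]

    def test_just_under_half_is_non_event(self):
        assert self._labels([Event(3.0, 4.99)]) == [0, 1]

    def test_disjoint_events_sum(self):
        assert self._labels([Event(0.0, 3.0), Event(5.0, 2.5)]) == [1, 0]

    def test_overlapping_events_merged_not_double_counted(self):
        # two 3 s events overlapping by 2 s cover only 4 s -> non-event
        assert self._labels([Event(0.0, 3.0), Event(1.0, 3.0)]) == [0, 1]

    def test_monotone_in_event_growth(self):
        rng = np.random.default_rng(3)
        segs = _segments(120.0, fs=20.0)
        for _ in range(20):
            onsets = np.sort(rng.uniform(0, 110, 4))
            durs = rng.uniform(1, 8, 4)
            events = [Event(float(o), float(d)) for o, d in zip(onsets, durs)]
            base = label_segments(segs, EventList(list(events)))
            grown = [
                Event(e.onset, e.duration + (2.0 if i == 1 else 0.0))
                for i, e in enumerate(events)
            ]
            bigger = label_segments(segs, EventList(grown))
            # growing an event can only flip windows toward the event class
            assert np.all(bigger.targets[:, 0] >= base.targets[:, 0])


def _labeled_set(n_events, n_non, fs=10.0, w=20, seed=0):
    rng = np.random.default_rng(seed)
    n = n_events + n_non
    targets = np.zeros((n, 2), dtype=np.int64)
    targets[:n_events, 0] = 1
    targets[n_events:, 1] = 1
    return SegmentSet(
        oral=rng.normal(size=(n, w)),
        nasal=rng.normal(size=(n, w)),
        targets=targets,
        subject_ids=np.array(["s"] * n, dtype=object),
        start_times=np.arange(n, dtype=float),
        fs=fs,
        window_s=w / fs,
        stride_s=w / fs,
    )


class TestDownsampleMajority:
    def test_two_percent_of_thousand(self):
        out = downsample_majority(_labeled_set(50, 1000), keep_fraction=0.02, seed=1)
        assert len(out) - out.n_events == 20
        assert out.n_events == 50

    def test_keep_all_is_permutation(self):
        segs = _labeled_set(10, 40)
        out = downsample_majority(segs, keep_fraction=1.0, seed=2)
        assert len(out) == 50
        assert sorted(out.start_times.tolist()) == sorted(segs.start_times.tolist())

    def test_deterministic_given_seed(self):
        a = downsample_majority(_labeled_set(5, 100), 0.1, seed=9)
        b = downsample_majority(_labeled_set(5, 100), 0.1, seed=9)
        assert np.array_equal(a.oral, b.oral)
        assert np.array_equal(a.targets, b.targets)

    def test_events_always_conserved(self):
        for seed in range(5):
            out = downsample_majority(_labeled_set(17, 500, seed=seed), 0.05, seed=seed)
            assert out.n_events == 17

    def test_no_non_events_returns_unchanged(self):
        segs = _labeled_set(10, 0)
        out = downsample_majority(segs, 0.5, seed=0)
        assert len(out) == 10


class TestSplitTrainTest:
    def test_test_size_rounds(self):
        train, test = split_train_test(_labeled_set(20, 80), test_fraction=0.33, seed=0)
        assert len(test) == 33
        assert len(train) == 67

    def test_stratification_within_one_window(self):
        _, test = split_train_test(_labeled_set(20, 80), test_fraction=0.33, seed=0)
        assert abs(test.n_events - round(0.33 * 20)) <= 1

    def test_deterministic(self):
        a1, b1 = split_train_test(_labeled_set(20, 80), 0.33, seed=5)
        a2, b2 = split_train_test(_labeled_set(20, 80), 0.33, seed=5)
        assert np.array_equal(a1.oral, a2.oral)
        assert np.array_equal(b1.targets, b2.targets)

    def test_both_halves_keep_both_classes(self):
        train, test = split_train_test(_labeled_set(3, 60), 0.33, seed=1)
        assert train.n_events >= 1 and test.n_events >= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(StratificationError):
            split_train_test(_labeled_set(1, 60), 0.33, seed=0)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        segs = _labeled_set(4, 16)
        path = segs.save(tmp_path / "segs.npz")
        back = SegmentSet.load(path)
        assert np.array_equal(back.targets, segs.targets)
        assert np.allclose(back.oral, segs.oral)
        assert back.fs == segs.fs and back.window_s == segs.window_s
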