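import numpy as np
import pytest

from erppipe.core_io import EpochSet, EventMarker, Recording
from erppipe.segmenter import (FasterSettings, PolicyError, RejectionPolicy,
                               SegmentationSettings, WindowError,
                               baseline_correct, faster_epoch_channel_flags,
                               interpolate_within_segments, reject_segments,
                               segment_events, split_by_condition)
from erppipe.sim_vep import hemisphere_montage


def recording_with_events(rate=1000.0, n=4000, events=(), n_ch=2, data=None):
    if data is None:
        data = np.zeros((n_ch, n))
    return Recording(data=data, rate=rate,
                     labels=[f"c{i}" for i in range(n_ch)],
                     events=[EventMarker(*e) for e in events])


class TestSegmentation:
    def test_epoch_sample_ranges(self):
        rec = recording_with_events(events=[("s", 1000), ("s", 1500)])
        rec.data[0] = np.arange(4000)
        eps = segment_events(rec, ["s"], SegmentationSettings((-100.0, 400.0)))
        assert eps.n_trials == 2
        assert eps.data.shape[2] == 500
        assert eps.data[0, 0, 0] == 900 and eps.data[0, 0, -1] == 1399
        assert eps.data[1, 0, 0] == 1400 and eps.data[1, 0, -1] == 1899

    def test_timing_offset_shifts_ranges(self):
        rec = recording_with_events(events=[("s", 1000)])
        rec.data[0] = np.arange(4000)
        eps = segment_events(rec, ["s"],
                             SegmentationSettings((-100.0, 400.0),
                                                  timing_offset_ms=16.0))
        assert eps.data[0, 0, 0] == 916

    def test_out_of_bounds_event_dropped(self):
        rec = recording_with_events(events=[("s", 50), ("s", 2000)])
        eps = segment_events(rec, ["s"], SegmentationSettings((-100.0, 400.0)))
        assert eps.n_trials == 1
        assert eps.n_dropped_events == 1

    def test_no_matching_events_noted_not_raised(self):
        rec = recording_with_events(events=[("other", 1000)])
        eps = segment_events(rec, ["s"], SegmentationSettings())
        assert eps.n_trials == 0
        assert any("no trials" in n for n in eps.notes)


class TestBaseline:
    def _eps(self, values):
        data = np.asarray(values, dtype=float)
        time = (np.arange(data.shape[2]) - 25) * 4.0
        return EpochSet(data=data, time=time, labels=["a"], rate=250.0)

    def test_constant_epoch_becomes_zero(self):
        eps = self._eps(np.full((1, 1, 125), 7.0))
        out = baseline_correct(eps, (-100.0, 0.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_step_epoch_keeps_difference(self):
        data = np.full((1, 1, 125), 9.0)
        data[0, 0, :26] = 2.0
        out = baseline_correct(self._eps(data), (-100.0, 0.0))
        np.testing.assert_allclose(out.data[0, 0, 30:], 7.0)

    def test_baseline_mean_is_zero_after(self, rng):
        eps = self._eps(rng.standard_normal((8, 1, 125)))
        out = baseline_correct(eps, (-100.0, 0.0))
        sel = (out.time >= -100) & (out.time <= 0)
        np.testing.assert_allclose(out.data[:, :, sel].mean(axis=2), 0.0,
                                   atol=1e-9)

    def test_empty_baseline_raises(self):
        eps = self._eps(np.zeros((1, 1, 125)))
        with pytest.raises(WindowError):
            baseline_correct(eps, (-0.5, -0.1))


class TestFasterFlags:
    def _eps(self, rng, trials=30, chans=4, samples=100):
        data = rng.standard_normal((trials, chans, samples))
        time = np.arange(samples) * 4.0
        return EpochSet(data=data, time=time,
                        labels=[f"c{i}" for i in range(chans)], rate=250.0)

    def test_scaled_trial_channel_flagged(self, rng):
        eps = self._eps(rng)
        eps.data[7, 2] *= 5.0
        flags = faster_epoch_channel_flags(eps)
        assert flags[7, 2]
        assert flags.sum() < 8  # isolated defect, few false flags

    def test_identical_trials_no_flags(self):
        data = np.tile(np.sin(np.arange(100) / 5.0), (10, 3, 1))
        eps = EpochSet(data=data, time=np.arange(100) * 4.0,
                       labels=["a", "b", "c"], rate=250.0)
        assert not faster_epoch_channel_flags(eps).any()

    def test_spike_flagged_via_amplitude_range(self, rng):
        eps = self._eps(rng)
        eps.data[3, 1, 50] += 300.0
        flags = faster_epoch_channel_flags(
            eps, FasterSettings(metrics=("amplitude_range",)))
        assert flags[3, 1]


class TestWithinSegmentInterpolation:
    def test_no_flags_identity(self, rng, montage32):
        labels = list(montage32.keys())
        eps = EpochSet(data=rng.standard_normal((5, 32, 50)),
                       time=np.arange(50) * 4.0, labels=labels, rate=250.0)
        out = interpolate_within_segments(
            eps, np.zeros((5, 32), dtype=bool), montage32)
        np.testing.assert_array_equal(out.data, eps.data)

    def test_smooth_field_reconstructed(self, montage32):
        labels = list(montage32.keys())
        pos = np.array(list(montage32.values()))
        field = pos[:, 2]
        data = np.tile(field[None, :, None], (4, 1, 50))
        eps = EpochSet(data=data.copy(), time=np.arange(50) * 4.0,
                       labels=labels, rate=250.0)
        flags = np.zeros((4, 32), dtype=bool)
        flags[2, 10] = True
        eps.data[2, 10] = 99.0
        out = interpolate_within_segments(eps, flags, montage32)
        err = np.abs(out.data[2, 10] - field[10]).max()
        assert err / np.sqrt(np.mean(field ** 2)) < 0.05
        assert out.interpolated_in_segment[2] == [labels[10]]

    def test_constant_field_exact(self, montage32):
        labels = list(montage32.keys())
        data = np.full((3, 32, 20), 4.5)
        eps = EpochSet(data=data, time=np.arange(20) * 4.0, labels=labels,
                       rate=250.0)
        flags = np.zeros((3, 32), dtype=bool)
        flags[1, 5] = True
        out = interpolate_within_segments(eps, flags, montage32)
        np.testing.assert_allclose(out.data[1, 5], 4.5, atol=1e-6)


class TestRejection:
    def _eps(self, rng, trials=12, chans=3, samples=100, scale=10.0):
        data = scale * rng.standard_normal((trials, chans, samples))
        return EpochSet(data=data, time=np.arange(samples) * 4.0,
                        labels=[f"c{i}" for i in range(chans)], rate=250.0)

    def test_amplitude_threshold_crossing_rejected(self, rng):
        eps = self._eps(rng)
        eps.data[4, 1, 10] = 151.0
        out, report = reject_segments(eps, RejectionPolicy("amplitude"))
        assert not out.kept[4]
        assert report.n_rejected == 1

    def test_identical_trials_survive_jointprob(self):
        data = np.tile(np.sin(np.arange(100) / 3.0), (10, 2, 1))
        eps = EpochSet(data=data, time=np.arange(100) * 4.0,
                       labels=["a", "b"], rate=250.0)
        out, report = reject_segments(eps, RejectionPolicy("jointprob"))
        assert report.n_rejected == 0

    def test_roi_ignores_artifact_elsewhere(self, rng):
        eps = self._eps(rng)
        eps.data[2, 0, 5] = 400.0  # artifact on non-ROI channel
        out, _ = reject_segments(
            eps, RejectionPolicy("amplitude", roi=["c1", "c2"]))
        assert out.kept[2]

    def test_roi_retains_at_least_as_many(self, rng):
        eps = self._eps(rng, scale=60.0)
        all_out, _ = reject_segments(eps, RejectionPolicy("amplitude"))
        roi_out, _ = reject_segments(
            eps, RejectionPolicy("amplitude", roi=["c0"]))
        assert roi_out.kept.sum() >= all_out.kept.sum()

    def test_widening_bounds_is_monotone(self, rng):
        eps = self._eps(rng, scale=60.0)
        narrow, _ = reject_segments(
            eps, RejectionPolicy("amplitude", amp_low=-100, amp_high=100))
        wide, _ = reject_segments(
            eps, RejectionPolicy("amplitude", amp_low=-200, amp_high=200))
        assert wide.kept.sum() >= narrow.kept.sum()
        # every trial kept under the narrow bound is kept under the wide one
        assert np.all(wide.kept[narrow.kept])

    def test_empty_roi_raises(self, rng):
        eps = self._eps(rng)
        with pytest.raises(PolicyError):
            reject_segments(eps, RejectionPolicy("amplitude", roi=["zz"]))

    def test_outlier_trial_caught_by_jointprob(self, rng):
        eps = self._eps(rng, trials=30)
        eps.data[11] = 10.0 * rng.standard_normal((3, 100)) ** 3  # heavy tails
        out, report = reject_segments(eps, RejectionPolicy("jointprob"))
        assert 11 in report.by_jointprob


class TestSplit:
    def _eps(self, conditions):
        n = len(conditions)
        data = np.arange(n)[:, None, None] * np.ones((1, 2, 10))
        return EpochSet(data=data, time=np.arange(10) * 4.0,
                        labels=["a", "b"], rate=250.0,
                        trial_conditions=list(conditions))

    def test_partition_counts(self):
        eps = self._eps(["A"] * 10 + ["B"] * 5)
        out = split_by_condition(eps)
        assert out["all"].n_trials == 15
        assert out["A"].n_trials == 10 and out["B"].n_trials == 5

    def test_condition_groups_merge_markers(self):
        eps = self._eps(["happy_face", "sad_face", "happy_face", "tone"])
        out = split_by_condition(eps, {"face": ["happy_face", "sad_face"]})
        assert out["face"].n_trials == 3

    def test_absent_marker_noted_empty(self):
        eps = self._eps(["A", "A"])
        out = split_by_condition(eps, {"C": ["C"]})
        assert out["C"].n_trials == 0
        assert any("no trials" in n for n in out["C"].notes)

    def test_no_trial_in_two_marker_sets(self):
        eps = self._eps(["A", "B", "A"])
        out = split_by_condition(eps)
        assert out["A"].n_trials + out["B"].n_trials == out["all"].n_trials
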