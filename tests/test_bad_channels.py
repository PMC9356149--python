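import numpy as np
import pytest

from erppipe.bad_channels import (BadChannelSettings, detect_bad_channels,
                                  detect_flatline, detect_line_ratio_outliers,
                                  detect_low_correlation,
                                  detect_spectral_outliers,
                                  channel_predictability)
from erppipe.core_io import Recording
from erppipe.sim_vep import pink_noise, synthesize_baseline


def pink_recording(n_ch, rate=250.0, dur=20.0, seed=0, scale=None):
    rng = np.random.default_rng(seed)
    data = pink_noise(int(dur * rate), rng, (n_ch,))
    if scale is not None:
        data = data * np.asarray(scale)[:, None]
    return Recording(data=data, rate=rate,
                     labels=[f"ch{i}" for i in range(n_ch)])


class TestFlatline:
    def test_constant_channel_flagged(self):
        assert detect_flatline(np.full(1500, 3.2), 250.0, 5.0)

    def test_exactly_five_seconds_not_flagged(self):
        rate = 250.0
        t = np.arange(int(20 * rate)) / rate
        x = 10 * np.sin(2 * np.pi * 3.1 * t + 0.37)
        x[1000:1000 + int(5.0 * rate)] = x[1000]  # run spans exactly 5.0 s
        assert not detect_flatline(x, rate, 5.0)
        x[1000:1000 + int(5.2 * rate)] = x[1000]
        assert detect_flatline(x, rate, 5.0)

    def test_sinusoid_not_flagged(self):
        t = np.arange(2500) / 250.0
        assert not detect_flatline(np.sin(2 * np.pi * 3 * t), 250.0, 5.0)


class TestSpectralOutliers:
    def test_power_scaled_channel_flagged(self):
        scale = np.ones(39)
        scale[7] = 8.0
        rec = pink_recording(39, seed=1, scale=scale)
        assert detect_spectral_outliers(rec) == {"ch7"}

    def test_identical_channels_none_flagged(self):
        base = pink_noise(5000, np.random.default_rng(2))
        rec = Recording(data=np.tile(base, (6, 1)), rate=250.0,
                        labels=[f"ch{i}" for i in range(6)])
        assert detect_spectral_outliers(rec) == set()

    def test_mildly_quiet_channel_spared(self):
        """Low-amplitude channels near a reference stay above the -5 SD bound.

        Channel gains spread naturally across the montage; a channel at
        70% amplitude sits around two SD below the mean log power, inside
        the deliberately lenient lower threshold.
        """
        rng = np.random.default_rng(33)
        scale = np.exp(0.15 * rng.standard_normal(39))
        scale[3] *= 0.7
        rec = pink_recording(39, seed=3, scale=scale)
        assert "ch3" not in detect_spectral_outliers(rec)


class TestLineRatio:
    def test_single_contaminated_channel_flagged(self):
        rec = pink_recording(20, seed=4)
        t = np.arange(rec.n_samples) / rec.rate
        rec.data[5] += 50.0 * np.sin(2 * np.pi * 60 * t)
        assert detect_line_ratio_outliers(rec, line_freq=60.0) == {"ch5"}

    def test_clean_recording_none_flagged(self):
        rec = pink_recording(20, seed=5)
        assert detect_line_ratio_outliers(rec, line_freq=60.0) == set()

    def test_uniform_contamination_none_flagged(self):
        rec = pink_recording(20, seed=6)
        t = np.arange(rec.n_samples) / rec.rate
        rec.data += 50.0 * np.sin(2 * np.pi * 60 * t)
        assert detect_line_ratio_outliers(rec, line_freq=60.0) == set()


class TestLowCorrelation:
    def test_independent_channel_flagged(self):
        rec = synthesize_baseline(24, 20.0, 250.0, seed=7)
        rng = np.random.default_rng(8)
        rec.data[10] = 10.0 * pink_noise(rec.n_samples, rng)
        flagged = detect_low_correlation(rec)
        assert rec.labels[10] in flagged
        assert len(flagged) == 1

    def test_duplicated_pair_not_flagged(self):
        rec = synthesize_baseline(24, 20.0, 250.0, seed=9)
        rec.data[3] = rec.data[4]
        assert detect_low_correlation(rec) == set()

    def test_threshold_straddle(self):
        """A channel mixed to sit just above/below 0.8 predictability."""
        rng = np.random.default_rng(10)
        common = pink_noise(5000, rng)
        data = np.stack([common + 0.05 * pink_noise(5000, rng)
                         for _ in range(6)])
        noise = pink_noise(5000, rng)

        def criterion(alpha):
            d = data.copy()
            d[0] = alpha * common + (1 - alpha) * noise
            rec = Recording(data=d, rate=250.0,
                            labels=[f"ch{i}" for i in range(6)])
            return channel_predictability(rec)[0], rec

        # calibrate the mixing coefficient to land at 0.81 and 0.79
        lo, hi = 0.0, 1.0
        for target, flag_expected in ((0.81, False), (0.79, True)):
            a, b = 0.0, 1.0
            for _ in range(40):
                mid = (a + b) / 2
                score, rec = criterion(mid)
                if score < target:
                    a = mid
                else:
                    b = mid
            score, rec = criterion((a + b) / 2)
            assert abs(score - target) < 0.005
            flagged = detect_low_correlation(rec)
            assert (rec.labels[0] in flagged) == flag_expected


class TestComposite:
    def test_clean_file_all_good(self):
        rec = synthesize_baseline(24, 20.0, 250.0, seed=11)
        report = detect_bad_channels(rec)
        assert report.bad_labels == []
        assert report.percent_good == 100.0

    def test_flat_and_power_channels_with_reasons(self):
        rec = synthesize_baseline(24, 20.0, 250.0, seed=12)
        rec.data[2] = 1.0
        rec.data[9] *= 8.0
        report = detect_bad_channels(rec)
        assert set(report.bad_labels) == {rec.labels[2], rec.labels[9]}
        assert report.criteria[rec.labels[2]] == ["flatline"]
        assert report.criteria[rec.labels[9]] == ["spectrum"]
        assert report.percent_good == pytest.approx(100 * 22 / 24)

    def test_added_flat_channel_does_not_disturb_others(self):
        rec = synthesize_baseline(24, 20.0, 250.0, seed=13)
        before = detect_bad_channels(rec)
        data = np.vstack([rec.data, np.zeros((1, rec.n_samples))])
        labels = rec.labels + ["flat"]
        montage = dict(rec.montage)
        montage["flat"] = (0.0, 0.0, 1.0)
        rec2 = Recording(data=data, rate=rec.rate, labels=labels,
                         montage=montage)
        after = detect_bad_channels(rec2)
        flat_before = {lb for lb, c in before.criteria.items()
                       if "flatline" in c}
        flat_after = {lb for lb, c in after.criteria.items()
                      if "flatline" in c and lb != "flat"}
        assert flat_before == flat_after
        assert "flatline" in after.criteria["flat"]

    def test_invariance_to_order_and_scale(self):
        rec = synthesize_baseline(20, 20.0, 250.0, seed=14)
        rec.data[4] *= 8.0
        base = set(detect_bad_channels(rec).bad_labels)
        perm = np.random.default_rng(1).permutation(20)
        rec_perm = Recording(
            data=rec.data[perm], rate=rec.rate,
            labels=[rec.labels[i] for i in perm],
            montage={rec.labels[i]: rec.montage[rec.labels[i]] for i in perm})
        assert set(detect_bad_channels(rec_perm).bad_labels) == base
        rec_scaled = rec.with_data(rec.data * 3.7)
        assert set(detect_bad_channels(rec_scaled).bad_labels) == base
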