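import numpy as np
import pytest

from erppipe.core_io import EpochSet
from erppipe.erp_measures import (DEFAULT_VEP_WINDOWS, AxisError, ERPWaveform,
                                  MeasureWindow, area_measures, average_trials,
                                  find_peaks, grand_average, mean_amplitude,
                                  measure_erp, peak_to_peak,
                                  zero_crossing_windows)
from erppipe.sim_vep import SimSettings, first_epoch_waveform


def wf(values, dt=1.0, t0=0.0):
    values = np.asarray(values, dtype=float)
    return ERPWaveform(values, t0 + np.arange(values.size) * dt)


class TestAverageTrials:
    def _eps(self, data):
        data = np.asarray(data, dtype=float)
        return EpochSet(data=data, time=np.arange(data.shape[2]) * 4.0,
                        labels=[f"c{i}" for i in range(data.shape[1])],
                        rate=250.0)

    def test_mean_over_trials(self):
        eps = self._eps(np.concatenate([np.full((1, 2, 10), 1.0),
                                        np.full((1, 2, 10), 3.0)]))
        out = average_trials(eps)
        np.testing.assert_allclose(out.values, 2.0)
        assert out.n_trials == 2

    def test_excluded_channel_ignored(self):
        data = np.ones((3, 2, 10))
        data[:, 1, :] = 1e6
        out = average_trials(self._eps(data), exclude=["c1"])
        np.testing.assert_allclose(out.values, 1.0)

    def test_single_trial_identity(self, rng):
        data = rng.standard_normal((1, 1, 20))
        out = average_trials(self._eps(data))
        np.testing.assert_allclose(out.values, data[0, 0])


class TestGrandAverage:
    def test_identical_waveforms_zero_se(self):
        w = wf(np.sin(np.arange(50) / 5.0))
        mean, se, lo, hi = grand_average([w, w, w])
        np.testing.assert_allclose(se, 0.0, atol=1e-12)
        np.testing.assert_allclose(lo, mean)

    def test_two_constants(self):
        mean, se, lo, hi = grand_average([wf(np.full(10, 1.0)),
                                          wf(np.full(10, 3.0))])
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(se, 1.0)
        np.testing.assert_allclose(hi - mean, 1.96)

    def test_axis_mismatch_raises(self):
        with pytest.raises(AxisError):
            grand_average([wf(np.zeros(10)), wf(np.zeros(11))])


class TestFindPeaks:
    def test_triangle_peak(self):
        values = np.concatenate([np.linspace(0, 5, 101),
                                 np.linspace(5, 0, 101)[1:]])
        erp = ERPWaveform(values, np.arange(values.size))
        res = find_peaks(erp, [MeasureWindow("P", 50, 150, "max")])
        assert res["windows"]["P"] == {"amplitude_uv": 5.0,
                                       "latency_ms": 100.0, "polarity": "max"}

    def test_simulated_vep_n1(self):
        """Gaussian-sum oracle: N1 window minimum -7.42 uV near 170 ms."""
        erp = first_epoch_waveform(settings=SimSettings(rate=1000.0))
        res = find_peaks(erp, DEFAULT_VEP_WINDOWS)
        n1 = res["windows"]["N1"]
        assert n1["amplitude_uv"] == pytest.approx(-7.42, abs=0.01)
        assert abs(n1["latency_ms"] - 170.0) <= 2.0

    def test_plateau_reports_earliest(self):
        values = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        res = find_peaks(ERPWaveform(values, np.arange(7.0)),
                         [MeasureWindow("P", 0, 6, "max")])
        assert res["windows"]["P"]["latency_ms"] == 2.0

    def test_local_extrema_listed(self):
        t = np.arange(200.0)
        values = np.sin(2 * np.pi * t / 100.0)
        res = find_peaks(ERPWaveform(values, t), [])
        assert [lat for _, lat in res["local_maxima"]] == [25.0, 125.0]
        assert [lat for _, lat in res["local_minima"]] == [75.0, 175.0]


class TestZeroCrossings:
    def test_full_sine_period_two_windows(self):
        t = np.arange(0, 200.0)
        windows = zero_crossing_windows(
            ERPWaveform(np.sin(2 * np.pi * (t + 0.5) / 200.0), t))
        assert len(windows) == 2

    def test_strictly_positive_single_window(self):
        erp = wf(np.full(50, 2.0))
        assert zero_crossing_windows(erp) == [(0.0, 49.0)]

    def test_exact_zero_is_boundary(self):
        values = np.array([1.0, 2.0, 0.0, 3.0, 1.0])
        windows = zero_crossing_windows(wf(values))
        assert (0.0, 2.0) in windows and (2.0, 4.0) in windows

    def test_windows_partition_axis(self, rng):
        erp = wf(rng.standard_normal(300))
        windows = zero_crossing_windows(erp)
        assert windows[0][0] == erp.time[0]
        assert windows[-1][1] == erp.time[-1]
        for (a, b), (c, d) in zip(windows[:-1], windows[1:]):
            assert b == c


class TestAmplitudeAndArea:
    def test_mean_amplitude_constant_and_ramp(self):
        assert mean_amplitude(wf(np.full(100, 3.3)), (0, 99)) == pytest.approx(3.3)
        ramp = wf(np.linspace(0, 10, 101))
        assert mean_amplitude(ramp, (0, 100)) == pytest.approx(5.0, abs=0.1)

    def test_mean_amplitude_half_sine(self):
        t = np.linspace(0, 100, 1001)
        values = 4.0 * np.sin(np.pi * t / 100.0)
        assert mean_amplitude(ERPWaveform(values, t), (0, 100)) == \
            pytest.approx(2 * 4.0 / np.pi, rel=0.01)

    def test_auc_rectangle(self):
        res = area_measures(wf(np.full(101, 2.0)), (0, 100))
        assert res["auc_uvms"] == pytest.approx(200.0)
        assert res["auc50_latency_ms"] == pytest.approx(50.0, abs=1.0)

    def test_auc_half_sine_closed_form(self):
        t = np.linspace(0, 80, 801)
        a = 3.0
        res = area_measures(ERPWaveform(a * np.sin(np.pi * t / 80.0), t),
                            (0, 80))
        assert res["auc_uvms"] == pytest.approx(2 * a * 80 / np.pi, rel=0.01)

    def test_global_absolute_auc_full_sine(self):
        t = np.linspace(0, 100, 2001)
        a = 2.0
        erp = ERPWaveform(a * np.sin(2 * np.pi * t / 100.0), t)
        res = area_measures(erp, (0, 100))
        assert res["global_abs_auc_uvms"] == pytest.approx(
            4 * a * 100 / (2 * np.pi), rel=0.01)

    def test_auc_additive_over_partition(self, rng):
        erp = wf(rng.standard_normal(200))
        windows = zero_crossing_windows(erp)
        total = area_measures(erp, (erp.time[0], erp.time[-1]))["auc_uvms"]
        parts = sum(area_measures(erp, w)["auc_uvms"] for w in windows)
        assert parts == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_auc50_latency_shifts_with_waveform(self):
        t = np.arange(0, 300.0)
        pulse = np.exp(-((t - 100) ** 2) / 200.0)
        lat1 = area_measures(ERPWaveform(pulse, t), (0, 299))["auc50_latency_ms"]
        shifted = np.exp(-((t - 150) ** 2) / 200.0)
        lat2 = area_measures(ERPWaveform(shifted, t), (0, 299))["auc50_latency_ms"]
        assert lat2 - lat1 == pytest.approx(50.0, abs=1.0)


class TestPeakToPeak:
    def test_printed_example(self):
        out = peak_to_peak([("N1", -7.42), ("P1", 8.61)])
        assert out["N1-P1"] == pytest.approx(16.03)

    def test_equal_peaks_zero(self):
        assert peak_to_peak([("a", 2.0), ("b", 2.0)])["a-b"] == 0.0

    def test_gaussian_sum_oracle_values(self):
        out = peak_to_peak([("N1", -7.42), ("P1", 6.38)])
        assert out["N1-P1"] == pytest.approx(13.80)


class TestMeasureTable:
    def test_row_contains_suite(self):
        erp = first_epoch_waveform(settings=SimSettings(rate=1000.0))
        row = measure_erp(erp, DEFAULT_VEP_WINDOWS, bound_mode="both")
        assert row["N1_amplitude_uv"] == pytest.approx(-7.42, abs=0.01)
        assert "N1-P1_uv" in row and "P1-N2_uv" in row
        assert row["N1_latency_ms"] >= 150.0
        assert "zero_crossing_areas" in row
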