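"""EEG preprocessing, spectra, Morlet maps, and relative-power summaries."""

import numpy as np
import pytest

from fesloop.imu import CycleSegmentation
from fesloop.spectral import (
    BANDS,
    EegRecording,
    TimeFrequencyMap,
    band_topography,
    bandpass_filter,
    common_average_reference,
    grand_average,
    morlet_cwt,
    power_spectrum,
    relative_power_db,
    segment_trials,
)

RATE = 512.0


def _rec(data, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return EegRecording(data=data, rate=RATE, labels=labels)


def _tone(freq, duration, rate=RATE, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestCAR:
    def test_identical_channels_become_zero(self):
        rec = _rec(np.full((4, 100), 3.7))
        out = common_average_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_two_channel_closed_form(self):
        a, b = np.sin(np.arange(50)), np.cos(np.arange(50))
        out = common_average_reference(_rec(np.vstack([a, b])))
        assert np.allclose(out.data[0], (a - b) / 2)
        assert np.allclose(out.data[1], (b - a) / 2)

    def test_channel_sum_zero_everywhere(self):
        rng = np.random.default_rng(0)
        out = common_average_reference(_rec(rng.normal(size=(16, 2000))))
        assert np.max(np.abs(out.data.sum(axis=0))) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(8, 500)))
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((1, 10))))


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        rec = _rec(_tone(2.0, 10.0))
        out = bandpass_filter(rec, 8.0, 45.0)
        assert np.std(out.data) < 0.1 * np.std(rec.data)

    def test_passband_tone_preserved(self):
        rec = _rec(_tone(20.0, 10.0))
        out = bandpass_filter(rec, 8.0, 45.0)
        mid = slice(int(2 * RATE), int(8 * RATE))  # avoid edge transients
        assert np.std(out.data[0, mid]) == pytest.approx(
            np.std(rec.data[0, mid]), rel=0.05
        )

    @pytest.mark.parametrize("freq", [4.0, 55.0])
    def test_design_attenuation_at_spec_points(self, freq):
        """>= 20 dB down at half the low edge and 10 Hz above the high edge."""
        rec = _rec(_tone(freq, 20.0))
        out = bandpass_filter(rec, 8.0, 45.0)
        mid = slice(int(5 * RATE), int(15 * RATE))
        atten = 20 * np.log10(np.std(rec.data[0, mid]) / np.std(out.data[0, mid]))
        assert atten >= 20.0

    def test_zero_signal_stays_zero(self):
        out = bandpass_filter(_rec(np.zeros((2, 4096))), 8.0, 45.0)
        assert np.allclose(out.data, 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec(np.zeros((2, 100))), 45.0, 8.0)

    def test_zero_phase_no_delay(self):
        x = _tone(10.0, 10.0)
        out = bandpass_filter(_rec(x), 8.0, 45.0)
        mid = slice(int(3 * RATE), int(7 * RATE))
        # correlation at zero lag should be maximal (no phase shift)
        r = np.corrcoef(x[mid], out.data[0, mid])[0, 1]
        assert r > 0.99


class TestSegmentTrials:
    def _segmentation(self, times):
        times = np.asarray(times, dtype=float)
        return CycleSegmentation((times * 20).astype(int), times)

    def test_ten_cycles_ten_trials(self):
        rec = _rec(np.random.default_rng(0).normal(size=(3, int(25 * RATE))))
        seg = self._segmentation(np.arange(0.5, 21.0, 2.0))  # 11 boundaries
        trials = segment_trials(rec, seg)
        assert trials.n_trials == seg.n_cycles == 10
        assert trials.data.shape == (10, 3, 101)

    def test_grid_points_echoed(self):
        rec = _rec(np.zeros((2, int(10 * RATE))))
        seg = self._segmentation([1.0, 3.0, 5.0])
        trials = segment_trials(rec, seg, grid_points=64)
        assert trials.data.shape[-1] == 64
        assert trials.cycle_percent[0] == 0.0 and trials.cycle_percent[-1] == 100.0

    def test_empty_segmentation_empty_matrix(self):
        rec = _rec(np.zeros((2, 1000)))
        trials = segment_trials(rec, CycleSegmentation(np.empty(0, int), np.empty(0)))
        assert trials.n_trials == 0

    def test_outlier_cycle_dropped_with_warning(self):
        rec = _rec(np.zeros((1, int(40 * RATE))))
        times = list(np.arange(0.5, 30.0, 2.0)) + [38.0]  # final 8 s cycle
        seg = self._segmentation(times)
        with pytest.warns(UserWarning, match="dropped"):
            trials = segment_trials(rec, seg)
        assert trials.n_trials == seg.n_cycles - 1
        assert trials.n_dropped == 1


class TestPowerSpectrum:
    def test_peak_at_tone_frequency(self):
        f, p = power_spectrum(_tone(10.0, 4.0), RATE)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=f[1] - f[0])

    def test_parseval_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4096)
        f, p = power_spectrum(x, RATE)
        total = p.sum() * (f[1] - f[0])
        assert total == pytest.approx(np.var(x), rel=1e-6)

    def test_zero_signal_zero_power(self):
        f, p = power_spectrum(np.zeros(1024), RATE)
        assert np.allclose(p, 0.0)

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2**16)
        f, p = power_spectrum(x, RATE)
        lo = p[(f > 10) & (f < 100)].mean()
        hi = p[(f > 150) & (f < 240)].mean()
        assert lo == pytest.approx(hi, rel=0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([1.0]), RATE)


class TestMorletCwt:
    def test_ridge_at_tone_frequency(self):
        freqs, power = morlet_cwt(_tone(10.0, 6.0), RATE)
        mid = power[:, power.shape[1] // 2]
        assert freqs[np.argmax(mid)] == pytest.approx(10.0, abs=0.5)

    def test_amplitude_step_localized_in_time(self):
        t = np.arange(int(8 * RATE)) / RATE
        x = np.sin(2 * np.pi * 25.0 * t) * (0.2 + 0.8 * (t >= 4.0))
        freqs, power = morlet_cwt(x, RATE, freqs=np.array([25.0]))
        before = power[0, int(2 * RATE) : int(3 * RATE)].mean()
        after = power[0, int(5 * RATE) : int(6 * RATE)].mean()
        assert after > 10 * before

    def test_zero_input_zero_power(self):
        _, power = morlet_cwt(np.zeros(4096), RATE)
        assert np.allclose(power, 0.0)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet_cwt(np.zeros(1024), RATE, freqs=np.array([300.0]))

    def test_cwt_and_periodogram_agree_on_peak(self):
        """Dual-route check: both estimators locate a stationary tone at the
        same grid frequency."""
        grid = np.arange(8.0, 45.0, 0.5)
        for tone_freq in (10.0, 22.5, 30.0):
            x = _tone(tone_freq, 8.0)
            freqs_c, power_c = morlet_cwt(x, RATE, freqs=grid)
            cwt_peak = grid[np.argmax(power_c.mean(axis=1))]
            f, p = power_spectrum(x, RATE)
            on_grid = np.interp(grid, f, p)
            fft_peak = grid[np.argmax(on_grid)]
            assert cwt_peak == fft_peak == pytest.approx(tone_freq, abs=0.25)


class TestRelativePower:
    def test_equal_powers_zero_db(self):
        x = np.ones(10)
        assert np.allclose(relative_power_db(x, x), 0.0)

    def test_doubling_is_3db(self):
        assert relative_power_db(np.array([2.0]), np.array([1.0]))[0] == pytest.approx(
            3.0103, abs=1e-3
        )

    def test_decade_is_10db(self):
        assert relative_power_db(np.array([0.1]), np.array([1.0]))[0] == pytest.approx(
            -10.0
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_power_db(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestBandTopography:
    def test_band_edges_exact(self):
        assert BANDS == {
            "mu": (8.0, 13.0),
            "low_beta": (13.0, 20.0),
            "high_beta": (20.0, 30.0),
        }

    def test_flat_zero_input_gives_zero_everywhere(self):
        freqs = np.arange(8.0, 45.0, 0.5)
        rel = np.zeros((16, freqs.size))
        labels = [f"e{i}" for i in range(16)]
        summary = band_topography(freqs, rel, labels, "mu")
        assert np.allclose(summary.power_db, 0.0)
        assert summary.labels == labels

    def test_mean_within_band_only(self):
        freqs = np.arange(8.0, 45.0, 1.0)
        rel = np.zeros((1, freqs.size))
        rel[0, (freqs >= 8) & (freqs <= 13)] = -6.0
        rel[0, freqs > 13] = 99.0  # outside the mu band, must be ignored
        summary = band_topography(freqs, rel, ["Cz"], "mu")
        assert summary.at("Cz") == pytest.approx(-6.0)

    def test_band_outside_spectrum_rejected(self):
        with pytest.raises(ValueError):
            band_topography(np.arange(30.0, 45.0), np.zeros((1, 15)), ["Cz"], "mu")

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            band_topography(np.arange(8.0, 45.0), np.zeros((1, 37)), ["Cz"], "gamma")


class TestGrandAverage:
    def _map(self, power):
        freqs = np.arange(power.shape[0], dtype=float) + 8.0
        percent = np.linspace(0, 100, power.shape[1])
        return TimeFrequencyMap(freqs, percent, power)

    def test_identical_trials_equal_single_trial(self):
        rng = np.random.default_rng(4)
        power = rng.uniform(0.5, 2.0, size=(5, 11))
        one = grand_average([self._map(power)])
        many = grand_average([self._map(power)] * 7)
        assert np.allclose(one.power, many.power)

    def test_rows_average_to_zero_db(self):
        rng = np.random.default_rng(5)
        maps = [self._map(rng.uniform(0.1, 3.0, size=(6, 21))) for _ in range(4)]
        out = grand_average(maps)
        assert np.allclose(out.power.mean(axis=1), 0.0, atol=1e-12)

    def test_variance_shrinks_with_trial_count(self):
        rng = np.random.default_rng(6)

        def spread(n):
            maps = [self._map(rng.lognormal(0.0, 0.5, size=(4, 15))) for _ in range(n)]
            return np.var(grand_average(maps).power)

        few = np.mean([spread(4) for _ in range(20)])
        many = np.mean([spread(64) for _ in range(20)])
        assert many < few / 8  # ~1/N scaling between N=4 and N=64

    def test_mismatched_grids_rejected(self):
        a = self._map(np.ones((4, 11)))
        b = TimeFrequencyMap(
            np.arange(4.0), np.linspace(0, 100, 12), np.ones((4, 12))
        )
        with pytest.raises(ValueError):
            grand_average([a, b])
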