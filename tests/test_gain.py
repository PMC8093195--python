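import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ephyskit.gain import (
    GainProfile,
    RateSignal,
    correlations,
    default_frequency_grid,
    firing_rate_signal,
    frequency_dependent_gain,
    groupwise_gain_comparison,
    spike_triggered_average,
)

FS = 10_000.0


class TestRateSignal:
    def test_single_spike_sample(self):
        r = firing_rate_signal(np.array([100]), 1000, FS)
        assert r.values[100] == FS
        assert np.sum(r.values != 0) == 1

    def test_no_spikes_all_zero(self):
        r = firing_rate_signal(np.array([], dtype=int), 1000, FS)
        assert not np.any(r.values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 9999), unique=True, max_size=50))
    def test_integral_equals_spike_count(self, idx):
        r = firing_rate_signal(np.array(sorted(idx), dtype=int), 10_000, FS)
        assert r.spike_count == pytest.approx(len(idx))

    def test_duplicate_spike_sample_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            firing_rate_signal(np.array([5, 5]), 100, FS)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            firing_rate_signal(np.array([100]), 100, FS)


class TestCorrelations:
    def test_rate_equal_stimulus_gives_identical_correlations(self, rng):
        s = rng.normal(0, 1, int(10 * FS))
        cp = correlations(s, RateSignal(s.copy(), 1 / FS), max_lag=0.5)
        np.testing.assert_allclose(cp.c_sr, cp.c_ss, rtol=1e-12)

    def test_autocorrelation_at_zero_estimates_variance(self, rng):
        n = int(100 * FS)
        s = rng.normal(0, 1, n)
        cp = correlations(s, RateSignal(s.copy(), 1 / FS), max_lag=0.1)
        se = np.sqrt(2.0 / n)
        assert abs(cp.c_ss[len(cp.c_ss) // 2] - 1.0) < 3 * se

    def test_fixed_delay_recovered_as_tau_delay(self, rng):
        s = rng.normal(0, 1, int(20 * FS))
        d = int(0.005 * FS)
        r = RateSignal(np.roll(s, d), 1 / FS)
        cp = correlations(s, r, max_lag=0.2)
        assert cp.tau_delay == pytest.approx(0.005, abs=1e-3)

    def test_constant_stimulus_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlations(np.ones(1000), RateSignal(np.zeros(1000), 1 / FS),
                         max_lag=0.01)


class TestFrequencyDependentGain:
    def test_identity_gain_and_phase(self, rng):
        s = rng.normal(0, 1, int(50 * FS))
        cp = correlations(s, RateSignal(s.copy(), 1 / FS), max_lag=1.0)
        gp = frequency_dependent_gain(cp)
        np.testing.assert_allclose(gp.gain, 1.0, atol=1e-6)
        np.testing.assert_allclose(gp.phase_raw, 0.0, atol=1e-6)

    def test_pure_delay_phase_and_correction(self, rng):
        s = rng.normal(0, 1, int(50 * FS))
        d = 0.005
        cp = correlations(s, RateSignal(np.roll(s, int(d * FS)), 1 / FS),
                          max_lag=1.0)
        gp = frequency_dependent_gain(cp)
        predicted = -2 * np.pi * gp.freqs * d
        wrapped_err = np.angle(np.exp(1j * (gp.phase_raw - predicted)))
        assert np.max(np.abs(wrapped_err)) < 0.05
        assert np.max(np.abs(gp.phase_corrected)) < 0.05

    def test_gain_scales_inversely_with_stimulus_amplitude(self, rng):
        s = rng.normal(0, 1, int(20 * FS))
        r = RateSignal(np.roll(s, 30), 1 / FS)
        freqs = np.array([5.0, 20.0, 60.0])
        g1 = frequency_dependent_gain(correlations(s, r, 0.5), freqs).gain
        g2 = frequency_dependent_gain(correlations(3.0 * s, r, 0.5), freqs).gain
        np.testing.assert_allclose(g2, g1 / 3.0, rtol=1e-9)
        # common rescaling of both leaves the gain unchanged
        r2 = RateSignal(3.0 * np.roll(s, 30), 1 / FS)
        g3 = frequency_dependent_gain(correlations(3.0 * s, r2, 0.5), freqs).gain
        np.testing.assert_allclose(g3, g1, rtol=1e-9)

    def test_default_grid_has_491_points(self):
        grid = default_frequency_grid()
        assert len(grid) == 491
        assert grid[0] == 2.0 and grid[-1] == 100.0

    def test_nonpositive_frequency_rejected(self, rng):
        s = rng.normal(0, 1, 10_000)
        cp = correlations(s, RateSignal(s.copy(), 1 / FS), max_lag=0.1)
        with pytest.raises(ValueError, match="positive"):
            frequency_dependent_gain(cp, np.array([0.0]))


class TestSTA:
    def test_random_spikes_give_flat_sta(self, rng):
        n = int(100 * FS)
        s = rng.normal(0, 1, n)
        idx = rng.choice(np.arange(int(0.2 * FS), n), 400, replace=False)
        sta = spike_triggered_average(s, idx, window=0.2, fs=FS)
        se = 1.0 / math.sqrt(400)
        assert np.max(np.abs(sta.sta)) < 4 * se  # ~2001 points, allow extremes

    def test_spikes_at_maxima_peak_at_zero_lag(self, rng):
        from scipy.signal import find_peaks

        n = int(50 * FS)
        s = rng.normal(0, 1, n)
        peaks, props = find_peaks(s, height=2.5)
        peaks = peaks[peaks > int(0.2 * FS)]
        sta = spike_triggered_average(s, peaks, window=0.2, fs=FS)
        assert np.argmax(sta.sta) == len(sta.sta) - 1
        mean_peak = s[peaks].mean() - s.mean()
        assert sta.sta[-1] == pytest.approx(mean_peak, rel=1e-9)

    def test_lag_grid_contract(self, rng):
        s = rng.normal(0, 1, int(10 * FS))
        sta = spike_triggered_average(s, np.array([50_000]), window=0.2, fs=FS)
        assert len(sta.lags) == 2001
        assert sta.lags[0] == -0.2 and sta.lags[-1] == 0.0

    def test_early_spikes_skipped_and_counted(self, rng):
        s = rng.normal(0, 1, int(1 * FS))
        sta = spike_triggered_average(s, np.array([100, 5000]), window=0.2, fs=FS)
        assert sta.n_spikes == 1
        with pytest.raises(ValueError, match="no spike"):
            spike_triggered_average(s, np.array([100]), window=0.2, fs=FS)


class TestGroupComparison:
    def _profile(self, gain, rate=10.0):
        grid = default_frequency_grid()
        return GainProfile(grid, np.full(len(grid), gain), np.zeros(len(grid)),
                           np.zeros(len(grid)), 0.005, rate)

    def test_identical_groups_nothing_significant(self, rng):
        grid = default_frequency_grid()
        cells = [
            GainProfile(grid, 0.1 + 0.01 * rng.standard_normal(len(grid)),
                        np.zeros(len(grid)), np.zeros(len(grid)), 0.005, 10.0)
            for _ in range(6)
        ]
        p, flags = groupwise_gain_comparison(cells, cells)
        assert not flags.any()

    def test_fully_separated_groups_give_exact_ranksum_p(self):
        a = [self._profile(0.1 + 0.001 * k) for k in range(8)]
        b = [self._profile(0.2 + 0.001 * k) for k in range(8)]
        p, flags = groupwise_gain_comparison(a, b)
        exact = 2 * (math.factorial(8) ** 2) / math.factorial(16)
        np.testing.assert_allclose(p, exact, rtol=1e-9)
        assert flags.all() and len(p) == 491

    def test_low_rate_cells_excluded(self):
        a = [self._profile(0.1, rate=10.0) for _ in range(2)]
        a += [self._profile(99.0, rate=2.0)]  # below the 5 Hz criterion
        b = [self._profile(0.2, rate=10.0) for _ in range(2)]
        p, _ = groupwise_gain_comparison(a, b)
        assert len(p) == 491  # ran with the low-rate cell dropped

    def test_mismatched_grids_rejected(self):
        a = [self._profile(0.1) for _ in range(2)]
        bad = GainProfile(np.arange(2.0, 50.0, 0.2), np.ones(240),
                          np.zeros(240), np.zeros(240), 0.0, 10.0)
        with pytest.raises(ValueError, match="grid"):
            groupwise_gain_comparison(a, [bad, bad])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            groupwise_gain_comparison([self._profile(0.1)],
                                      [self._profile(0.2)] * 3)
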