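import numpy as np
import pytest

from ephyskit.io import SweepRecord, SweepSet
from ephyskit.protocols import ZapProtocol, make_zap
from ephyskit.resonance import (
    compare_densities,
    impedance_profile,
    spike_probability_density,
)
from ephyskit.sim import ModelParams, simulate

FS = 10_000.0


def _zap_sweep(voltage, current, fs=FS, onset=0.0, offset=None):
    n = len(voltage)
    return SweepRecord("c", voltage, current, fs, stim_onset=onset,
                       stim_offset=n / fs if offset is None else offset)


def _simulated_zap_trial(p: ModelParams, zap: ZapProtocol, seed=0, rest=0.5):
    cmd, _ = make_zap(zap)
    pad = np.zeros(int(rest * FS))
    full = np.concatenate([pad, cmd, pad])
    res = simulate(p, full, FS, stim_onset=rest,
                   stim_offset=rest + zap.duration, seed=seed)
    return res.sweep


class TestImpedanceProfile:
    def test_identical_series_give_unit_ratio(self):
        zap = ZapProtocol(amplitude=10.0)
        cmd, _ = make_zap(zap)
        # voltage = command + offset: after mean removal the ratio is unity
        prof = impedance_profile(SweepSet([_zap_sweep(cmd - 50.0, cmd)], [10.0]), zap)
        # mV/pA is GΩ: a unit ratio is 1000 MΩ flat across the band
        np.testing.assert_allclose(prof.z_mag, 1e3, rtol=1e-9)

    def test_rc_membrane_matches_closed_form_and_is_nonresonant(self):
        p = ModelParams(gh=0.0, spike_mechanism="none", noise_sd=0.0,
                        C=200.0, gL=10.0)
        zap = ZapProtocol(amplitude=20.0)
        prof = impedance_profile(
            SweepSet([_simulated_zap_trial(p, zap)], [20.0]), zap
        )
        rc = 100.0 / np.sqrt(1 + (2 * np.pi * prof.freqs * 100e6 * 200e-12) ** 2)
        np.testing.assert_allclose(prof.z_mag, rc, rtol=0.02)
        assert np.all(np.diff(prof.z_mag) < 1e-3)
        assert not prof.resonant

    def test_quasi_active_cell_is_resonant_at_linearized_peak(self):
        from ephyskit.sim import _steady_state, linearized_impedance

        p = ModelParams(gh=15.0, tau_h=80.0, spike_mechanism="none", noise_sd=0.0)
        zap = ZapProtocol(amplitude=10.0)
        prof = impedance_profile(
            SweepSet([_simulated_zap_trial(p, zap)], [10.0]), zap
        )
        v0, _ = _steady_state(p)
        grid = np.arange(0.5, 20.0, 0.01)
        fr_analytic = grid[np.argmax(linearized_impedance(p, v0, grid))]
        assert prof.resonant
        assert abs(prof.fR - fr_analytic) <= 0.5  # one smoothing window

    def test_normalized_magnitude_invariant_to_stimulus_scale(self):
        p = ModelParams(gh=0.0, spike_mechanism="none", noise_sd=0.0)
        zap1, zap2 = ZapProtocol(amplitude=10.0), ZapProtocol(amplitude=30.0)
        prof1 = impedance_profile(SweepSet([_simulated_zap_trial(p, zap1)], [10.0]), zap1)
        prof2 = impedance_profile(SweepSet([_simulated_zap_trial(p, zap2)], [30.0]), zap2)
        np.testing.assert_allclose(prof1.z_mag_norm, prof2.z_mag_norm, atol=1e-4)
        assert prof1.z_mag_norm.max() == 1.0

    def test_spiking_trials_rejected_with_warning(self):
        p_sub = ModelParams(gh=0.0, spike_mechanism="none", noise_sd=0.0)
        zap = ZapProtocol(amplitude=10.0)
        good = _simulated_zap_trial(p_sub, zap)
        bad = good.with_series(voltage=good.voltage.copy())
        bad.voltage[5000:5003] = 20.0  # an overshoot spike
        with pytest.warns(UserWarning, match="excluded"):
            prof = impedance_profile(SweepSet([good, bad], [10.0, 10.0]), zap)
        assert prof.n_trials_averaged == 1
        with pytest.raises(ValueError, match="spikes"):
            impedance_profile(SweepSet([bad], [10.0]), zap)


class TestSpikeProbabilityDensity:
    def _trials_with_spikes_at(self, spike_times_per_trial, zap, onset=0.0):
        sweeps = []
        n = int(zap.duration * FS) + int(onset * FS)
        for times in spike_times_per_trial:
            v = np.full(n, -65.0)
            for t in times:
                k = int((t + onset) * FS)
                v[k] = 20.0  # overshoot peak
            sweeps.append(_zap_sweep(v, np.zeros(n), onset=onset,
                                     offset=onset + zap.duration))
        return SweepSet(sweeps, [0.0] * len(sweeps))

    def test_mass_concentrates_in_known_frequency_bin(self):
        zap = ZapProtocol(f0=1.0, f1=20.0, duration=20.0)
        # inst freq f(t) = 1 + 0.95 t; f in [4, 5] Hz <=> t in [3.16, 4.21] s
        trials = self._trials_with_spikes_at(
            [[3.3, 3.6], [3.9, 4.1]], zap
        )
        dens = spike_probability_density(trials, zap, bin_width_hz=1.0)
        k = np.searchsorted(dens.bin_edges, 4.0)
        assert dens.probability[k] == pytest.approx(1.0)
        assert dens.probability.sum() == pytest.approx(1.0)
        assert dens.n_spikes_total == 4

    def test_single_spike_density(self):
        zap = ZapProtocol()
        dens = spike_probability_density(
            self._trials_with_spikes_at([[10.0]], zap), zap
        )
        assert dens.n_spikes_total == 1
        assert dens.probability.max() == pytest.approx(1.0)

    def test_zero_spikes_flagged_empty(self):
        zap = ZapProtocol()
        with pytest.warns(UserWarning, match="no spikes"):
            dens = spike_probability_density(
                self._trials_with_spikes_at([[]], zap), zap
            )
        assert dens.n_spikes_total == 0
        assert dens.probability.sum() == 0.0

    def test_band_restriction_partitions_the_samples(self):
        zap = ZapProtocol()
        dens = spike_probability_density(
            self._trials_with_spikes_at([[2.0, 8.0, 14.0, 19.0]], zap), zap
        )
        lo = dens.spike_frequencies[dens.spike_frequencies <= 12.0]
        hi = dens.spike_frequencies[dens.spike_frequencies > 12.0]
        assert sorted(np.concatenate([lo, hi])) == sorted(dens.spike_frequencies)


class TestCompareDensities:
    def _dens(self, samples):
        from ephyskit.resonance import SpikeFrequencyDensity

        samples = np.asarray(samples, float)
        return SpikeFrequencyDensity(
            bin_edges=np.arange(1.0, 21.0),
            probability=np.histogram(samples, np.arange(1.0, 21.0))[0] / len(samples),
            n_spikes_total=len(samples),
            spike_frequencies=samples,
        )

    def test_identical_samples(self):
        a = self._dens([2.0, 5.0, 9.0, 15.0])
        d, p = compare_densities(a, a)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = compare_densities(self._dens([2.0, 3.0, 4.0]),
                                 self._dens([15.0, 16.0, 17.0]))
        assert d == 1.0

    def test_band_restriction_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            compare_densities(self._dens([2.0]), self._dens([3.0]),
                              band=(12.0, 20.0))

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        for _ in range(200):
            a = self._dens(rng.normal(10.0, 2.0, 200))
            b = self._dens(rng.normal(10.0, 2.0, 200))
            _, p = compare_densities(a, b)
            rejections += p < 0.05
        assert abs(rejections / 200 - 0.05) <= 0.03
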