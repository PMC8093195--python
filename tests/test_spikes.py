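import numpy as np
import pytest

from ephyskit.io import SweepRecord, SweepSet
from ephyskit.protocols import step_command
from ephyskit.spikes import (
    APWaveformFeatures,
    TrainFeatures,
    ap_waveform_features,
    classify_cell,
    detect_spikes,
    train_features,
)

FS = 10_000.0


def _sweep(v, amplitude=0.0, pre=0.1, dur=0.6, fs=FS):
    v = np.asarray(v, float)
    cmd = np.zeros_like(v)
    n_pre, n_dur = int(pre * fs), int(dur * fs)
    cmd[n_pre: n_pre + n_dur] = amplitude
    return SweepRecord("c", v, cmd, fs, stim_onset=pre, stim_offset=pre + dur)


def _trace_with_triangular_spikes(times, fs=FS, duration=1.0, baseline=-65.0,
                                  thr=-40.0, peak=40.0, rise_ms=1.0, fall_ms=1.0):
    """Triangular APs with a slow (5 mV/ms) sub-criterion approach ramp from
    baseline to threshold, so the dV/dt threshold criterion lands at thr."""
    v = np.full(int(duration * fs), baseline)
    n_r = int(rise_ms / 1000 * fs)
    n_f = int(fall_ms / 1000 * fs)
    n_a = int((thr - baseline) / 5.0 / 1000 * fs)  # approach at 5 mV/ms
    n_d = int((thr - baseline) / 10.0 / 1000 * fs)  # repolarize at 10 mV/ms
    for t in times:
        k = int(t * fs)
        v[k - n_r - n_a: k - n_r] = np.linspace(baseline, thr, n_a + 1)[:-1]
        v[k - n_r: k] = np.linspace(thr, peak, n_r + 1)[:-1]
        v[k: k + n_f] = np.linspace(peak, thr, n_f + 1)[:-1]
        v[k + n_f: k + n_f + n_d] = np.linspace(thr, baseline, n_d + 1)[:-1]
    return v


class TestDetection:
    def test_overshoot_counts_sinusoid_peaks(self):
        t = np.arange(int(1.0 * FS)) / FS
        v = -30.0 + 40.0 * np.sin(2 * np.pi * 5 * t)  # peaks at +10 mV
        train = detect_spikes(_sweep(v), mode="overshoot")
        assert len(train) == 5

    def test_subthreshold_trace_has_no_spikes(self):
        t = np.arange(int(1.0 * FS)) / FS
        v = -60.0 + 30.0 * np.sin(2 * np.pi * 5 * t)  # never above −20 mV
        assert len(detect_spikes(_sweep(v), mode="overshoot")) == 0

    @pytest.mark.parametrize("mode", ["overshoot", "dvdt"])
    def test_constructed_spike_times_recovered(self, mode):
        times = [0.2, 0.35, 0.52, 0.8]
        v = _trace_with_triangular_spikes(times)
        train = detect_spikes(_sweep(v), mode=mode)
        np.testing.assert_allclose(train.spike_times, times, atol=1.5 / FS)

    def test_voltage_clamp_sweep_rejected(self):
        sweep = SweepRecord("c", np.zeros(100), np.zeros(100), FS,
                            clamp_mode="voltage")
        with pytest.raises(ValueError, match="current-clamp"):
            detect_spikes(sweep)

    def test_overshoot_count_monotone_under_negative_offset(self):
        v = _trace_with_triangular_spikes([0.2, 0.4, 0.6], peak=10.0)
        base = len(detect_spikes(_sweep(v), mode="overshoot"))
        shifted = len(detect_spikes(_sweep(v - 15.0), mode="overshoot"))
        assert shifted <= base


class TestAPWaveform:
    def test_symmetric_triangle_geometry(self):
        v = _trace_with_triangular_spikes([0.3], thr=-40.0, peak=40.0,
                                          rise_ms=1.0, fall_ms=1.0)
        feats = ap_waveform_features(SweepSet([_sweep(v, 200.0)], [200.0]))
        assert feats.amplitude == pytest.approx(80.0, abs=2.0)
        assert feats.half_width == pytest.approx(1.0, abs=0.1)
        assert feats.upstroke_downstroke_ratio == pytest.approx(1.0, abs=0.05)
        assert feats.peak == pytest.approx(40.0, abs=0.5)

    def test_asymmetric_triangle_upstroke_downstroke(self):
        v = _trace_with_triangular_spikes([0.3], rise_ms=0.5, fall_ms=1.0)
        feats = ap_waveform_features(SweepSet([_sweep(v, 200.0)], [200.0]))
        assert feats.upstroke_downstroke_ratio == pytest.approx(2.0, abs=0.15)

    def test_latency_references_stimulus_onset(self):
        v = _trace_with_triangular_spikes([0.3])
        feats = ap_waveform_features(SweepSet([_sweep(v, 200.0)], [200.0]))
        assert feats.latency == pytest.approx(200.0, abs=1.0)  # ms

    def test_simulated_threshold_recovered_within_1mv(self, l5_step_family):
        from ephyskit.sim import ModelParams

        feats = ap_waveform_features(l5_step_family)
        assert feats.threshold == pytest.approx(ModelParams().spike_cut, abs=1.0)

    def test_no_suprathreshold_sweep_is_error(self):
        v = np.full(int(1.0 * FS), -65.0)
        with pytest.raises(ValueError, match="suprathreshold"):
            ap_waveform_features(SweepSet([_sweep(v, 200.0)], [200.0]))


class TestTrainFeatures:
    def _family(self, counts_by_amp, first_isis=None):
        """Build a family where sweep at amp has k evenly spread spikes."""
        sweeps, amps = [], []
        for amp, k in counts_by_amp.items():
            if k:
                times = 0.15 + 0.5 * np.arange(k) / max(k, 1)
                if first_isis and amp in first_isis:
                    times = 0.15 + np.concatenate([[0.0], np.cumsum(first_isis[amp])])
                v = _trace_with_triangular_spikes(times)
            else:
                v = np.full(int(1.0 * FS), -65.0)
            sweeps.append(_sweep(v, amp))
            amps.append(amp)
        return SweepSet(sweeps, amps)

    def test_rheobase_and_fi_slope(self):
        fam = self._family({100.0: 0, 150.0: 3, 200.0: 6})
        tf = train_features(fam)
        assert tf.rheobase == 150.0
        assert tf.fi_slope == pytest.approx((6 - 3) / 0.6 / 50.0)

    def test_constant_isis_give_zero_adaptation_and_cv(self):
        fam = self._family({150.0: 1, 200.0: 5},
                           first_isis={200.0: [0.05, 0.05, 0.05, 0.05]})
        tf = train_features(fam)
        assert tf.adaptation_index == pytest.approx(0.0, abs=1e-9)
        assert tf.isi_cv == pytest.approx(0.0, abs=1e-9)

    def test_adaptation_index_of_10_20_ms_isis(self):
        fam = self._family({150.0: 1, 200.0: 3},
                           first_isis={200.0: [0.010, 0.020]})
        tf = train_features(fam)
        assert tf.adaptation_index == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert tf.isi_first == pytest.approx(10.0, abs=0.2)

    def test_hero_sweep_is_rheobase_plus_50(self):
        fam = self._family({100.0: 2, 150.0: 4, 200.0: 8})
        tf = train_features(fam)
        assert tf.rheobase == 100.0
        assert tf.hero_amplitude == 150.0
        assert tf.avg_rate_hero == pytest.approx(4 / 0.6)
        assert not tf.hero_flagged

    def test_missing_hero_window_falls_back_with_flag(self):
        fam = self._family({100.0: 2, 200.0: 8})
        with pytest.warns(UserWarning, match="rheobase"):
            tf = train_features(fam)
        assert tf.hero_flagged and tf.hero_amplitude == 200.0

    def test_no_spiking_sweep_is_error(self):
        fam = self._family({100.0: 0, 200.0: 0})
        with pytest.raises(ValueError, match="no spiking"):
            train_features(fam)


class TestClassification:
    def _ap(self, hw=1.8, ahp=8.0):
        return APWaveformFeatures(threshold=-45.0, peak=35.0, amplitude=80.0,
                                  half_width=hw, upstroke_downstroke_ratio=2.0,
                                  ahp_amplitude=ahp, latency=50.0)

    def _train(self, isi_rheo=np.nan, isi_p50=np.nan, max_rate=20.0):
        return TrainFeatures(rheobase=150.0, fi_slope=0.1, adaptation_index=0.1,
                             isi_first=20.0, isi_mean=30.0, isi_median=30.0,
                             isi_cv=0.2, avg_rate_hero=10.0, hero_amplitude=200.0,
                             isi_first_rheobase=isi_rheo,
                             isi_first_rheo_plus50=isi_p50, max_rate=max_rate)

    def test_83hz_first_isi_is_bursting_at_rheobase(self):
        cls = classify_cell(self._ap(), self._train(isi_rheo=12.0))
        assert cls.bursting == "at_rheobase"

    def test_bursting_at_rheobase_plus_50_category(self):
        cls = classify_cell(self._ap(), self._train(isi_rheo=30.0, isi_p50=10.0))
        assert cls.bursting == "at_rheobase_plus_50"

    def test_interneuron_criteria_all_required(self):
        fast = classify_cell(self._ap(hw=0.8, ahp=12.0),
                             self._train(max_rate=90.0))
        assert fast.cell_class == "putative_interneuron"
        # each single criterion failing reverts to pyramidal
        for kw, tr in [(dict(hw=1.2, ahp=12.0), dict(max_rate=90.0)),
                       (dict(hw=0.8, ahp=8.0), dict(max_rate=90.0)),
                       (dict(hw=0.8, ahp=12.0), dict(max_rate=50.0))]:
            got = classify_cell(self._ap(**kw), self._train(**tr))
            assert got.cell_class == "pyramidal"

    def test_regular_pyramid(self):
        cls = classify_cell(self._ap(), self._train(isi_rheo=40.0, isi_p50=25.0))
        assert cls.cell_class == "pyramidal" and cls.bursting == "none"
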