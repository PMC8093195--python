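import numpy as np
import pytest

from ephyskit.io import SweepRecord, SweepSet
from ephyskit.sim import ModelParams, simulate_vclamp
from ephyskit.vclamp import (
    IhStepResult,
    activation_curve,
    ih_kinetics,
    ih_step_amplitudes,
)

FS = 10_000.0


def _clamp_family(p: ModelParams, steps=None):
    steps = steps if steps is not None else np.arange(-60.0, -150.0, -10.0)
    sweeps, amps = [], []
    for v_step in steps:
        cmd = np.full(int(1.1 * FS), -60.0)
        cmd[int(0.2 * FS): int(0.8 * FS)] = v_step
        sweeps.append(simulate_vclamp(p, cmd, FS, stim_onset=0.2, stim_offset=0.8))
        amps.append(float(v_step))
    return SweepSet(sweeps, amps)


def _boltzmann(v, v50, k):
    return 1.0 / (1.0 + np.exp((v - v50) / k))


class TestStepAmplitudes:
    def test_synthetic_relaxation_amplitude(self):
        """Current stepping −100 pA instantaneous → −180 pA steady reads out
        as an 80 pA Ih amplitude."""
        n = int(1.1 * FS)
        t = np.arange(n) / FS
        cur = np.zeros(n)
        on, off = int(0.2 * FS), int(0.8 * FS)
        tau = 0.05
        seg = t[on:off] - t[on]
        cur[on:off] = -180.0 + 80.0 * np.exp(-seg / tau)
        sweep = SweepRecord("c", np.full(n, -60.0), cur, FS,
                            clamp_mode="voltage", stim_onset=0.2, stim_offset=0.8)
        res = ih_step_amplitudes(SweepSet([sweep] * 9, list(np.arange(-60., -150., -10.))))
        # instantaneous window 10–30 ms: exp has decayed to exp(-0.4)-ish
        expected = 180.0 - (180.0 - 80.0 * np.exp(-0.02 / tau))
        assert res.ih_amplitude[3] == pytest.approx(expected, rel=0.1)

    def test_gh_zero_cell_has_no_ih(self):
        res = ih_step_amplitudes(
            _clamp_family(ModelParams(gh=0.0, spike_mechanism="none"))
        )
        assert np.all(res.ih_amplitude < 1.0)
        assert np.all(res.tail_amplitude[1:] < 1.0)

    def test_simulated_hcn_matches_gating_closed_form(self):
        p = ModelParams(gh=5.0, spike_mechanism="none")
        res = ih_step_amplitudes(_clamp_family(p))
        m_hold = float(p.m_inf(-60.0))
        for v_step, amp in zip(res.step_potentials, res.ih_amplitude):
            if v_step == -60.0:
                continue
            m_inf = float(p.m_inf(v_step))
            # relaxation from the end of the instantaneous window onward
            full = abs(p.gh * (m_inf - m_hold) * (v_step - p.Eh))
            remaining = np.exp(-20.0 / p.tau_h) - np.exp(-575.0 / p.tau_h)
            assert amp == pytest.approx(full * remaining, rel=0.05)

    def test_tail_amplitudes_grow_with_hyperpolarization(self):
        res = ih_step_amplitudes(_clamp_family(ModelParams(gh=5.0, spike_mechanism="none")))
        tails = res.tail_amplitude
        assert np.all(np.diff(tails) >= -0.5)  # monotone within noise
        assert tails[-1] > 10 * max(tails[0], 0.1)

    def test_partial_family_flagged(self):
        fam = _clamp_family(ModelParams(gh=5.0, spike_mechanism="none"),
                            steps=[-60.0, -100.0, -140.0])
        with pytest.warns(UserWarning, match="partial"):
            res = ih_step_amplitudes(fam)
        assert res.flagged

    def test_current_clamp_input_rejected(self):
        sweep = SweepRecord("c", np.zeros(100), np.zeros(100), FS)
        with pytest.raises(ValueError, match="voltage-clamp"):
            ih_step_amplitudes(SweepSet([sweep]))


class TestActivationCurve:
    def _result(self, tails, pots=None):
        pots = pots if pots is not None else np.arange(-60.0, -150.0, -10.0)
        return IhStepResult(np.asarray(pots), np.zeros(len(pots)),
                            np.asarray(tails, float), -60.0)

    def test_noiseless_recovery_within_0p1_percent(self):
        pots = np.arange(-60.0, -150.0, -10.0)
        tails = 120.0 * _boltzmann(pots, -90.0, 9.0) + 5.0
        act = activation_curve(self._result(tails))
        assert act.v50 == pytest.approx(-90.0, abs=0.09)
        assert act.k == pytest.approx(9.0, rel=1e-3)

    def test_v50_bias_under_2_percent_noise(self):
        pots = np.arange(-60.0, -150.0, -10.0)
        clean = 120.0 * _boltzmann(pots, -90.0, 9.0)
        v50s = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * (1.0 + rng.normal(0, 0.02, len(clean)))
            v50s.append(activation_curve(self._result(noisy)).v50)
        assert abs(np.mean(v50s) - (-90.0)) < 1.0

    def test_fit_is_idempotent(self):
        pots = np.arange(-60.0, -150.0, -10.0)
        tails = 80.0 * _boltzmann(pots, -95.0, 7.0) + 2.0
        first = activation_curve(self._result(tails))
        refit_tails = _boltzmann(pots, first.v50, first.k)
        second = activation_curve(self._result(refit_tails))
        assert second.v50 == pytest.approx(first.v50, abs=1e-6)
        assert second.k == pytest.approx(first.k, abs=1e-6)

    def test_activation_increases_with_hyperpolarization(self):
        res = ih_step_amplitudes(_clamp_family(ModelParams(gh=5.0, spike_mechanism="none")))
        act = activation_curve(res)
        assert act.activation[-1] > act.activation[0]
        assert np.all((0.0 <= act.activation) & (act.activation <= 1.0))

    def test_equal_tails_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            act = activation_curve(self._result(np.full(9, 50.0)))
        assert act.degenerate

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            activation_curve(self._result([1.0, 2.0, 3.0],
                                          pots=[-60.0, -70.0, -80.0]))


class TestKinetics:
    def test_single_exponential_recovered_within_1_percent(self):
        t = np.arange(int(0.6 * FS)) / FS * 1e3
        y = -120.0 + 60.0 * np.exp(-t / 200.0)
        kin = ih_kinetics(y, FS)
        assert kin.model == "single"
        assert kin.tau_fast == pytest.approx(200.0, rel=0.01)

    def test_double_exponential_recovered_within_5_percent(self):
        t = np.arange(int(2.0 * FS)) / FS * 1e3
        y = -100.0 + 30.0 * np.exp(-t / 50.0) + 30.0 * np.exp(-t / 500.0)
        kin = ih_kinetics(y, FS)
        assert kin.model == "double"
        assert kin.tau_fast == pytest.approx(50.0, rel=0.05)
        assert kin.tau_slow == pytest.approx(500.0, rel=0.05)
        assert kin.tau_fast < kin.tau_slow

    def test_flat_trace_is_error(self):
        with pytest.raises(ValueError, match="flat"):
            ih_kinetics(np.full(1000, -100.0), FS)
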