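"""Passive-membrane and sag/rebound features from hyperpolarizing steps.

Definitions:

* sag amplitude = V_steady − V_min during a hyperpolarizing step (mV),
  measured by default on the −400 pA sweep;
* sag ratio = (V_steady − V_min) / (V_baseline − V_min), dimensionless,
  the sag normalized by the peak deflection;
* rebound amplitude = post-step maximum (spike samples masked) minus the
  pre-step baseline;
* input resistance = slope of steady-state ΔV against injected current
  over sweeps between −50 and −200 pA; membrane time constant from a
  single-exponential fit to each step onset, averaged.

Windows (the steady-state and baseline averages use the final 100 ms of
the step and of the pre-stimulus period respectively) are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import SweepRecord, SweepSet

__all__ = [
    "PassiveFeatures",
    "resting_potential",
    "input_resistance_and_tau",
    "sag_features",
    "rebound_features",
    "passive_features",
]

BASELINE_WINDOW = 0.1  # s before stimulus onset
STEADY_WINDOW = 0.1  # s at end of step
RIN_AMP_RANGE = (-200.0, -50.0)  # pA, sweeps used for Rin / tau_m


@dataclass
class PassiveFeatures:
    rmp: float  # mV
    input_resistance: float  # MΩ (nan when undefined)
    tau_m: float  # ms (nan when undefined)
    sag_amplitude: float  # mV
    sag_ratio: float
    rebound_amplitude: float  # mV
    rebound_spike_count: int
    sag_measured_at: float  # pA


def _baseline(sweep: SweepRecord, window: float = BASELINE_WINDOW) -> float:
    i1 = sweep.sample_of(sweep.stim_onset)
    i0 = max(0, i1 - sweep.sample_of(window))
    return float(np.mean(sweep.voltage[i0:i1]))


def _steady(sweep: SweepRecord, window: float = STEADY_WINDOW) -> float:
    i1 = sweep.sample_of(sweep.stim_offset)
    i0 = max(sweep.sample_of(sweep.stim_onset), i1 - sweep.sample_of(window))
    return float(np.mean(sweep.voltage[i0:i1]))


def resting_potential(sweeps: SweepSet, zero_tol: float = 1.0) -> float:
    """Mean pre-stimulus voltage over sweeps held at zero current.

    Requires at least one sweep with a pre-stimulus window of >= 100 ms at
    zero holding current (|median pre-stimulus current| <= ``zero_tol`` pA).
    """
    values = []
    for sweep in sweeps:
        n_on = sweep.sample_of(sweep.stim_onset)
        if n_on < sweep.sample_of(BASELINE_WINDOW):
            continue
        holding = float(np.median(sweep.current[:n_on]))
        if abs(holding) <= zero_tol:
            values.append(_baseline(sweep))
    if not values:
        raise ValueError(
            "no sweep with a >=100 ms zero-current pre-stimulus window"
        )
    return float(np.mean(values))


def _fit_onset_exponential(sweep: SweepRecord) -> float:
    """Membrane time constant (ms) from the voltage onset of one step.

    Fits V(t) = V0 + A (1 − exp(−t/τ)) from step onset to the first local
    extremum, which precedes any sag rebound.
    """
    fs = sweep.sampling_rate
    i_on = sweep.sample_of(sweep.stim_onset)
    i_off = sweep.sample_of(sweep.stim_offset)
    seg = sweep.voltage[i_on:i_off]
    i_ext = int(np.argmin(seg))  # hyperpolarizing steps: minimum
    i_ext = max(i_ext, int(0.005 * fs))
    seg = seg[: i_ext + 1]
    t = np.arange(len(seg)) / fs * 1000.0  # ms

    def model(tt, v0, amp, tau):
        return v0 + amp * (1.0 - np.exp(-tt / tau))

    tau0 = max(1.0, len(seg) / fs * 1000.0 / 3.0)
    try:
        popt, _ = curve_fit(
            model, t, seg, p0=[seg[0], seg[-1] - seg[0], tau0],
            maxfev=5000,
        )
    except RuntimeError:
        return float("nan")
    tau = float(popt[2])
    return tau if 0 < tau < 1e4 else float("nan")


def input_resistance_and_tau(sweeps: SweepSet) -> tuple[float, float]:
    """(Rin MΩ, tau_m ms) from hyperpolarizing sweeps in [−200, −50] pA.

    Rin is the least-squares slope of steady-state ΔV against injected
    current; tau_m is the mean onset-fit time constant. With fewer than
    two qualifying sweeps Rin is returned as nan (flagged by a warning).
    """
    amps, dvs, taus = [], [], []
    for sweep, amp in zip(sweeps.sweeps, sweeps.amplitudes):
        if not (RIN_AMP_RANGE[0] <= amp <= RIN_AMP_RANGE[1]):
            continue
        dvs.append(_steady(sweep) - _baseline(sweep))
        amps.append(amp)
        tau = _fit_onset_exponential(sweep)
        if np.isfinite(tau):
            taus.append(tau)
    if len(amps) < 2:
        warnings.warn("fewer than 2 sweeps in [-200, -50] pA; Rin undefined",
                      stacklevel=2)
        rin = float("nan")
    else:
        slope = np.polyfit(np.asarray(amps), np.asarray(dvs), 1)[0]  # mV/pA = GΩ
        rin = float(slope * 1e3)  # MΩ
    if not taus:
        warnings.warn("no convergent onset exponential; tau_m undefined",
                      stacklevel=2)
        tau_m = float("nan")
    else:
        tau_m = float(np.mean(taus))
    return rin, tau_m


def sag_features(sweep: SweepRecord) -> tuple[float, float]:
    """(sag amplitude mV, sag ratio) for one hyperpolarizing step sweep."""
    i_on = sweep.sample_of(sweep.stim_onset)
    i_off = sweep.sample_of(sweep.stim_offset)
    step_current = float(np.median(sweep.current[i_on:i_off]))
    if step_current >= 0:
        raise ValueError("sag is defined on hyperpolarizing steps only")
    v_base = _baseline(sweep)
    v_min = float(np.min(sweep.voltage[i_on:i_off]))
    v_ss = _steady(sweep)
    amplitude = v_ss - v_min
    if v_base - v_min <= 0:
        warnings.warn("no hyperpolarizing deflection; sag ratio undefined",
                      stacklevel=2)
        return amplitude, float("nan")
    return amplitude, amplitude / (v_base - v_min)


def rebound_features(
    sweep: SweepRecord, min_post_window: float = 0.3, spike_mask_ms: float = 5.0
) -> tuple[float, int]:
    """(rebound amplitude mV, rebound spike count) after a hyperpolarizing step.

    The amplitude references the pre-stimulus baseline; samples within
    ``spike_mask_ms`` of a detected rebound spike are masked before
    taking the post-step maximum.
    """
    from .spikes import detect_spikes

    fs = sweep.sampling_rate
    i_off = sweep.sample_of(sweep.stim_offset)
    if sweep.n_samples - i_off < sweep.sample_of(min_post_window):
        raise ValueError(
            f"post-stimulus window shorter than {min_post_window*1e3:.0f} ms"
        )
    v_base = _baseline(sweep)
    post = sweep.voltage[i_off:].copy()
    train = detect_spikes(sweep, mode="overshoot")
    post_spikes = train.spike_times[train.spike_times >= sweep.stim_offset]
    half = int(spike_mask_ms / 1000.0 * fs)
    for t_spk in post_spikes:
        k = int(round(t_spk * fs)) - i_off
        post[max(0, k - half): k + half + 1] = -np.inf
    finite = post[np.isfinite(post)]
    amplitude = float(np.max(finite) - v_base) if finite.size else float("nan")
    return amplitude, int(len(post_spikes))


def passive_features(
    sweeps: SweepSet, sag_sweep_amplitude: float = -400.0
) -> PassiveFeatures:
    """All passive features of one cell from its step family."""
    rmp = resting_potential(sweeps)
    rin, tau_m = input_resistance_and_tau(sweeps)
    try:
        sag_sweep = sweeps.sweep_at(sag_sweep_amplitude)
        sag_at = sag_sweep_amplitude
    except KeyError:
        neg = [a for a in sweeps.amplitudes if a < 0]
        if not neg:
            raise ValueError("no hyperpolarizing sweep for sag measurement")
        sag_at = min(neg)
        sag_sweep = sweeps.sweep_at(sag_at)
    sag_amp, sag_ratio = sag_features(sag_sweep)
    reb_amp, reb_n = rebound_features(sag_sweep)
    return PassiveFeatures(
        rmp=rmp,
        input_resistance=rin,
        tau_m=tau_m,
        sag_amplitude=sag_amp,
        sag_ratio=sag_ratio,
        rebound_amplitude=reb_amp,
        rebound_spike_count=reb_n,
        sag_measured_at=sag_at,
    )
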