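"""Voltage-clamp quantification of the hyperpolarization-activated
current Ih: step amplitudes, tail currents, Boltzmann activation curve,
and exponential kinetics.

Protocol: 600-ms voltage steps from a −60 mV holding potential down to
−140 mV in −10 mV increments. Per step, the Ih amplitude is the absolute
difference between the steady-state current at the end of the step and
the instantaneous current just after the capacitive transient; the tail
amplitude is the residual current peak on return to holding, relative to
the steady holding current. Normalized tails against step potential give
the activation curve, fitted with a Boltzmann sigmoid
A(V) = 1/(1 + exp((V − V50)/k)); in-step relaxations are fitted with
single or double exponentials (small-sample AIC selects the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import SweepSet

__all__ = [
    "IhStepResult",
    "ActivationCurve",
    "IhKinetics",
    "ih_step_amplitudes",
    "activation_curve",
    "ih_kinetics",
]

BLANK_WINDOW = 0.010  # s after each transition (capacitive transient)
INSTANT_WINDOW = (0.010, 0.030)  # s after step onset
STEADY_WINDOW = 0.050  # s at end of step
TAIL_SEARCH = 0.150  # s after return to holding
AIC_MARGIN = 2.0  # double-exponential must beat single by this much


@dataclass
class IhStepResult:
    step_potentials: np.ndarray  # mV, strictly decreasing
    ih_amplitude: np.ndarray  # pA per step
    tail_amplitude: np.ndarray  # pA per step (magnitude)
    holding: float  # mV
    flagged: bool = False  # True when steps were missing


@dataclass
class ActivationCurve:
    step_potentials: np.ndarray  # mV
    activation: np.ndarray  # normalized 0..1
    v50: float  # mV
    k: float  # mV
    residual: float
    degenerate: bool = False


@dataclass
class IhKinetics:
    model: str  # single | double
    tau_fast: float  # ms
    tau_slow: float  # ms (nan for single)
    fraction_fast: float  # amplitude fraction of the fast component


def ih_step_amplitudes(
    sweeps: SweepSet,
    blank: float = BLANK_WINDOW,
    instant_window: tuple[float, float] = INSTANT_WINDOW,
    steady_window: float = STEADY_WINDOW,
) -> IhStepResult:
    """Ih and tail amplitudes for each voltage step of a clamp family."""
    if sweeps.clamp_mode != "voltage":
        raise ValueError("Ih quantification requires voltage-clamp sweeps")
    order = np.argsort(sweeps.amplitudes)[::-1]  # −60 first, −140 last
    pots, ih_amps, tail_amps = [], [], []
    expected = np.arange(-60.0, -150.0, -10.0)
    for k in order:
        sweep = sweeps.sweeps[k]
        v_step = sweeps.amplitudes[k]
        fs = sweep.sampling_rate
        i_on = sweep.sample_of(sweep.stim_onset)
        i_off = sweep.sample_of(sweep.stim_offset)
        holding = float(np.median(sweep.voltage[: max(1, i_on)])) if i_on else -60.0
        cur = sweep.current
        inst = np.mean(cur[i_on + int(instant_window[0] * fs):
                           i_on + int(instant_window[1] * fs)])
        steady = np.mean(cur[i_off - int(steady_window * fs): i_off])
        ih_amps.append(abs(float(steady - inst)))
        # tail: residual-current extremum after return to holding, minus the
        # steady holding current at the end of the post period
        j0 = i_off + int(blank * fs)
        j1 = min(sweep.n_samples, i_off + int(TAIL_SEARCH * fs))
        post_end = np.mean(cur[-int(steady_window * fs):])
        if j1 > j0:
            seg = cur[j0:j1]
            peak = seg[np.argmax(np.abs(seg - post_end))]
            tail_amps.append(abs(float(peak - post_end)))
        else:
            tail_amps.append(float("nan"))
        pots.append(float(v_step))
    flagged = len(pots) < len(expected)
    if flagged:
        warnings.warn(
            f"only {len(pots)} of {len(expected)} expected steps present; "
            "partial result", stacklevel=2,
        )
    return IhStepResult(
        step_potentials=np.asarray(pots),
        ih_amplitude=np.asarray(ih_amps),
        tail_amplitude=np.asarray(tail_amps),
        holding=-60.0,
        flagged=flagged,
    )


def _boltzmann(v, v50, k):
    return 1.0 / (1.0 + np.exp(np.clip((v - v50) / k, -500, 500)))


def activation_curve(step_result: IhStepResult) -> ActivationCurve:
    """Boltzmann fit of the tail-current activation curve.

    Tails are fitted with base + amp · Boltzmann(V; V50, k) so the
    normalization does not bias V50 and k when the protocol does not span
    the full activation range; the reported activation is
    (tail − base)/amp clipped to [0, 1].
    """
    v = step_result.step_potentials
    tails = step_result.tail_amplitude
    ok = np.isfinite(tails)
    v, tails = v[ok], tails[ok]
    if len(v) < 5:
        raise ValueError("activation curve needs >= 5 steps with tails")
    span = tails.max() - tails.min()
    if span <= 0 or span < 1e-9 * max(1.0, abs(tails.max())):
        warnings.warn("all tail amplitudes equal; fit degenerate", stacklevel=2)
        return ActivationCurve(v, np.zeros_like(tails), float("nan"),
                               float("nan"), float("nan"), degenerate=True)

    def model(vv, base, amp, v50, k):
        return base + amp * _boltzmann(vv, v50, k)

    p0 = [tails.min(), span, float(np.median(v)), 9.0]
    try:
        with warnings.catch_warnings():
            # near-noiseless tails make the covariance singular; irrelevant here
            from scipy.optimize import OptimizeWarning
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, v, tails, p0=p0, maxfev=10000)
    except RuntimeError:
        warnings.warn("Boltzmann fit did not converge", stacklevel=2)
        return ActivationCurve(v, (tails - tails.min()) / span, float("nan"),
                               float("nan"), float(np.inf), degenerate=True)
    base, amp, v50, k = popt
    if amp < 0:  # absorb sign so k > 0 means activation with hyperpolarization
        base, amp = base + amp, -amp
        k = -k
    act = np.clip((tails - base) / amp, 0.0, 1.0)
    resid = float(np.sqrt(np.mean((model(v, *popt) - tails) ** 2)))
    return ActivationCurve(v, act, float(v50), float(abs(k)), resid)


def _fit_exponentials(t, y):
    """Return ((sse, params, n_params) for single, double) or None on failure."""
    y0, y1 = y[0], y[-1]
    tau0 = max(t[-1] / 3.0, 1e-3)

    def single(tt, c, a, tau):
        return c + a * np.exp(-tt / tau)

    def double(tt, c, a1, tau1, a2, tau2):
        return c + a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    out = {}
    try:
        p1, _ = curve_fit(single, t, y, p0=[y1, y0 - y1, tau0], maxfev=10000)
        out["single"] = (float(np.sum((single(t, *p1) - y) ** 2)), p1, 3)
    except RuntimeError:
        pass
    try:
        p2, _ = curve_fit(
            double, t, y,
            p0=[y1, 0.5 * (y0 - y1), tau0 / 4.0, 0.5 * (y0 - y1), tau0 * 2.0],
            maxfev=20000,
        )
        out["double"] = (float(np.sum((double(t, *p2) - y) ** 2)), p2, 5)
    except RuntimeError:
        pass
    return out


def ih_kinetics(trace: np.ndarray, fs: float, margin: float = AIC_MARGIN) -> IhKinetics:
    """Time constants of an in-step Ih relaxation (capacitive part removed).

    Fits single and double exponentials; the double model is selected only
    when its small-sample-corrected AIC improves on the single model by
    more than ``margin``.
    """
    y = np.asarray(trace, dtype=float)
    if np.ptp(y) < 1e-9 * max(1.0, np.abs(y).max()) or np.ptp(y) == 0:
        raise ValueError("flat trace: no relaxation to fit")
    t = np.arange(len(y)) / fs * 1e3  # ms
    fits = _fit_exponentials(t, y)
    if not fits:
        raise ValueError("neither exponential model converged")
    n = len(y)

    def aicc(sse, k):
        aic = n * np.log(max(sse, 1e-300) / n) + 2 * k
        return aic + 2 * k * (k + 1) / max(n - k - 1, 1)

    use_double = (
        "double" in fits
        and ("single" not in fits
             or aicc(*[fits["double"][0], fits["double"][2]])
             < aicc(*[fits["single"][0], fits["single"][2]]) - margin)
    )
    if use_double:
        _, p2, _ = fits["double"]
        _, a1, tau1, a2, tau2 = p2
        (tf, af), (ts, as_) = sorted([(abs(tau1), a1), (abs(tau2), a2)])
        return IhKinetics("double", float(tf), float(ts),
                          float(abs(af) / (abs(af) + abs(as_))))
    _, p1, _ = fits["single"]
    return IhKinetics("single", float(abs(p1[2])), float("nan"), 1.0)
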