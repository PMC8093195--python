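"""Synthetic single-compartment neuron with HCN current and adaptive
exponential spiking.

The model integrates

    C dV/dt = -gL (V - EL) - gh m (V - Eh) - w + I_exp + I(t) + noise
    dm/dt   = (m_inf(V) - m) / tau_h,   m_inf(V) = 1 / (1 + exp((V - V50h)/kh))
    dw/dt   = (a (V - EL) - w) / tau_w

with, when spiking is enabled, the exponential spike-initiation term
I_exp = gL * DeltaT * exp((V - VT)/DeltaT). When V crosses the numerical
spike cut a stereotyped suprathreshold action-potential waveform
(peak > 0 mV, so overshoot detection applies) is pasted into the output
voltage, w is incremented by b, and integration resumes from the
waveform's after-hyperpolarization trough. Pasting keeps ground-truth
spike times exact for detector tests.

Units: mV, ms, pA, pF, nS throughout the integrator (pA/pF = mV/ms).
Integration is fixed-step (the stimulus sampling interval, optionally
subdivided) and deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .io import SweepRecord, SweepSet
from .protocols import (
    NoiseProtocol,
    ZapProtocol,
    make_current_steps,
    make_frozen_filtered_noise,
    make_zap,
    step_command,
)

__all__ = [
    "ModelParams",
    "SimResult",
    "simulate",
    "simulate_vclamp",
    "linearized_impedance",
    "ArchetypeSpec",
    "CohortCell",
    "default_layer_archetypes",
    "classification_archetypes",
    "make_cohort",
    "write_cohort",
]


@dataclass
class ModelParams:
    """Parameters of the single-compartment model (defaults: a human
    L5-like regular-spiking pyramidal cell)."""

    C: float = 200.0  # pF
    gL: float = 10.0  # nS
    EL: float = -70.0  # mV
    gh: float = 4.0  # nS
    Eh: float = -30.0  # mV
    V50h: float = -90.0  # mV, half-activation (activates with hyperpolarization)
    kh: float = 9.0  # mV, activation steepness
    tau_h: float = 50.0  # ms
    spike_mechanism: str = "adex"  # none | adex
    VT: float = -55.0  # mV, exponential-term threshold
    DeltaT: float = 2.0  # mV
    Vreset: float = -53.0  # mV (informational; reset lands at the AHP trough)
    a: float = 2.0  # nS, subthreshold adaptation
    b: float = 100.0  # pA, spike-triggered adaptation
    tau_w: float = 150.0  # ms
    ap_peak: float = 35.0  # mV, pasted AP peak
    ap_half_width: float = 1.8  # ms, pasted AP width at half amplitude
    ap_updown_ratio: float = 2.5  # upstroke/downstroke dV/dt ratio
    ap_ahp: float = 8.0  # mV, AHP depth below spike threshold
    noise_sd: float = 0.0  # pA, intrinsic white current noise (per sample)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.gL, self.tau_h, self.tau_w) <= 0:
            raise ValueError("C, gL, tau_h, tau_w must be > 0")
        if self.gh < 0 or self.kh <= 0:
            raise ValueError("require gh >= 0 and kh > 0")
        if self.spike_mechanism not in ("none", "adex"):
            raise ValueError("spike_mechanism must be 'none' or 'adex'")

    @property
    def spike_cut(self) -> float:
        """Numerical divergence cut that triggers a spike (mV)."""
        return self.VT + 5.0 * self.DeltaT

    def m_inf(self, v):
        return 1.0 / (1.0 + np.exp(np.clip((np.asarray(v, float) - self.V50h) / self.kh, -50, 50)))

    def ap_waveform(self, fs: float) -> tuple[np.ndarray, int]:
        """Stereotyped AP sampled at fs; returns (waveform mV, peak index).

        Rise spike_cut -> ap_peak over t_r, fall back to spike_cut over
        t_f = ratio * t_r with (t_r + t_f)/2 = half width, then descent to
        the AHP trough (spike_cut - ap_ahp) over 2 ms.
        """
        rho = self.ap_updown_ratio
        t_r = 2.0 * self.ap_half_width / (1.0 + rho)
        t_f = rho * t_r
        t_ahp = 2.0
        thr = self.spike_cut
        n_r = max(2, int(round(t_r * fs / 1000.0)))
        n_f = max(2, int(round(t_f * fs / 1000.0)))
        n_a = max(2, int(round(t_ahp * fs / 1000.0)))
        rise = np.linspace(thr, self.ap_peak, n_r + 1)[:-1]
        fall = np.linspace(self.ap_peak, thr, n_f + 1)[:-1]
        ahp = np.linspace(thr, thr - self.ap_ahp, n_a + 1)[1:]
        wave = np.concatenate([rise, fall, ahp])
        return wave, n_r


@dataclass
class SimResult:
    sweep: SweepRecord
    spike_times: np.ndarray  # s
    gating: np.ndarray  # HCN activation m per sample
    adaptation: np.ndarray  # w (pA) per sample
    params: ModelParams


@njit(cache=False)
def _run_cc(stim, noise, dt, nsub, C, gL, EL, gh, Eh, V50, kh, tauh,
            spiking, VT, DT, vcut, a, b, tauw, wave, peak_off, v0, m0, w0):
    n = stim.shape[0]
    nw = wave.shape[0]
    V = np.empty(n)
    M = np.empty(n)
    W = np.empty(n)
    spk = np.empty(n, np.int64)
    nspk = 0
    v, m, w = v0, m0, w0
    h = dt / nsub
    i = 0
    while i < n:
        drive = stim[i] + noise[i]
        spiked = False
        for _ in range(nsub):
            iexp = 0.0
            if spiking:
                ex = (v - VT) / DT
                if ex > 25.0:
                    ex = 25.0
                iexp = gL * DT * np.exp(ex)
            dv = (-gL * (v - EL) - gh * m * (v - Eh) - w + iexp + drive) / C
            v = v + h * dv
            ex2 = (v - V50) / kh
            if ex2 > 50.0:
                ex2 = 50.0
            elif ex2 < -50.0:
                ex2 = -50.0
            minf = 1.0 / (1.0 + np.exp(ex2))
            m = m + h * (minf - m) / tauh
            if spiking:
                w = w + h * (a * (v - EL) - w) / tauw
            if spiking and v >= vcut:
                spiked = True
                break
        if spiked:
            # paste stereotyped AP; gating/adaptation follow the pasted voltage
            if i + peak_off < n:
                spk[nspk] = i + peak_off
                nspk += 1
            w = w + b
            j = 0
            while j < nw and i + j < n:
                vp = wave[j]
                V[i + j] = vp
                ex2 = (vp - V50) / kh
                if ex2 > 50.0:
                    ex2 = 50.0
                elif ex2 < -50.0:
                    ex2 = -50.0
                minf = 1.0 / (1.0 + np.exp(ex2))
                m = m + dt * (minf - m) / tauh
                w = w + dt * (a * (vp - EL) - w) / tauw
                M[i + j] = m
                W[i + j] = w
                j += 1
            v = wave[nw - 1]
            i += j
        else:
            V[i] = v
            M[i] = m
            W[i] = w
            i += 1
    return V, M, W, spk[:nspk]


@njit(cache=False)
def _run_vc(vcmd, dt, nsub, C, gL, EL, gh, Eh, V50, kh, tauh, m0):
    n = vcmd.shape[0]
    I = np.empty(n)
    M = np.empty(n)
    m = m0
    h = dt / nsub
    for i in range(n):
        v = vcmd[i]
        for _ in range(nsub):
            ex2 = (v - V50) / kh
            if ex2 > 50.0:
                ex2 = 50.0
            elif ex2 < -50.0:
                ex2 = -50.0
            minf = 1.0 / (1.0 + np.exp(ex2))
            m = m + h * (minf - m) / tauh
        icap = 0.0
        if i > 0:
            icap = C * (vcmd[i] - vcmd[i - 1]) / dt
        I[i] = gL * (v - EL) + gh * m * (v - Eh) + icap
        M[i] = m
    return I, M


def _steady_state(p: ModelParams) -> tuple[float, float]:
    """Resting fixed point (V, m) with zero input (spike term off)."""
    v = p.EL
    for _ in range(200):
        m = float(p.m_inf(v))
        v_new = (p.gL * p.EL + p.gh * m * p.Eh) / (p.gL + p.gh * m)
        if abs(v_new - v) < 1e-10:
            v = v_new
            break
        v = v_new
    return v, float(p.m_inf(v))


def simulate(
    p: ModelParams,
    stimulus: np.ndarray,
    fs: float,
    nsub: int = 2,
    cell_id: str = "sim",
    layer_label: str = "unknown",
    protocol_id: str = "",
    stim_onset: float = 0.0,
    stim_offset: float | None = None,
    seed: int | None = None,
) -> SimResult:
    """Integrate the model under a current stimulus (pA, sampled at fs).

    Deterministic for fixed parameters and seed; ``nsub`` substeps per
    stimulus sample control integration accuracy without changing the
    noise realization (noise is held constant within a sample).
    """
    stimulus = np.ascontiguousarray(stimulus, dtype=float)
    if not np.all(np.isfinite(stimulus)):
        raise ValueError("stimulus must be finite")
    if fs < 10_000.0:
        raise ValueError("sampling rate must be >= 10 kHz")
    dt = 1000.0 / fs  # ms
    use_seed = p.seed if seed is None else seed
    if p.noise_sd > 0:
        rng = np.random.default_rng(int(use_seed) % 2**31)
        noise = rng.normal(0.0, p.noise_sd, len(stimulus))
    else:
        noise = np.zeros_like(stimulus)
    v0, m0 = _steady_state(p)
    spiking = p.spike_mechanism == "adex"
    wave, peak_off = p.ap_waveform(fs)
    V, M, W, spk = _run_cc(
        stimulus, noise, dt, int(nsub), p.C, p.gL, p.EL, p.gh, p.Eh,
        p.V50h, p.kh, p.tau_h, spiking, p.VT, p.DeltaT, p.spike_cut,
        p.a, p.b, p.tau_w, wave, int(peak_off), v0, m0, 0.0,
    )
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("numerical divergence outside spike handling")
    sweep = SweepRecord(
        cell_id=cell_id,
        layer_label=layer_label,
        protocol_id=protocol_id,
        voltage=V,
        current=stimulus,
        sampling_rate=fs,
        clamp_mode="current",
        stim_onset=stim_onset,
        stim_offset=len(stimulus) / fs if stim_offset is None else stim_offset,
    )
    return SimResult(sweep, spk / fs, M, W, p)


def simulate_vclamp(
    p: ModelParams,
    v_command: np.ndarray,
    fs: float,
    nsub: int = 2,
    cell_id: str = "sim",
    protocol_id: str = "vclamp",
    stim_onset: float = 0.0,
    stim_offset: float | None = None,
) -> SweepRecord:
    """Ideal voltage clamp: returns the clamp current (pA) for a command
    potential series (mV); leak + Ih only, with a one-sample capacitive
    transient at command transitions."""
    v_command = np.ascontiguousarray(v_command, dtype=float)
    dt = 1000.0 / fs
    m0 = float(p.m_inf(v_command[0]))
    I, _ = _run_vc(v_command, dt, int(nsub), p.C, p.gL, p.EL, p.gh, p.Eh,
                   p.V50h, p.kh, p.tau_h, m0)
    return SweepRecord(
        cell_id=cell_id,
        protocol_id=protocol_id,
        voltage=v_command,
        current=I,
        sampling_rate=fs,
        clamp_mode="voltage",
        stim_onset=stim_onset,
        stim_offset=len(v_command) / fs if stim_offset is None else stim_offset,
    )


def linearized_impedance(
    p: ModelParams, v_star: float, freqs: np.ndarray
) -> np.ndarray:
    """Quasi-active (small-signal) impedance magnitude |Z(f)| in MΩ.

    Linearizing the membrane + HCN gating around V*:

        Z(f) = [ g_tot + i 2πf C + gh (V* − Eh) m_inf'(V*) / (1 + i 2πf τ_h) ]⁻¹

    with g_tot = gL + gh m_inf(V*). The gating term acts as a
    phenomenological inductance and can produce a resonant peak.
    """
    if p.spike_mechanism != "none":
        raise ValueError("linearization applies to the non-spiking model")
    freqs = np.asarray(freqs, dtype=float)
    minf = float(p.m_inf(v_star))
    dminf = -minf * (1.0 - minf) / p.kh  # per mV
    g_tot = p.gL + p.gh * minf  # nS
    omega = 2 * np.pi * freqs
    # nS units: C pF -> 1e-3 nF gives nS when multiplied by rad/s... use SI-free mix:
    # i*omega*C with C in pF and omega in 1/s gives pS = 1e-3 nS.
    admittance = (
        g_tot
        + 1j * omega * p.C * 1e-3
        + p.gh * (v_star - p.Eh) * dminf / (1.0 + 1j * omega * p.tau_h * 1e-3)
    )  # nS
    z_gohm = 1.0 / admittance
    return np.abs(z_gohm) * 1e3  # MΩ


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class ArchetypeSpec:
    """A parameter distribution for one cell archetype.

    ``jitter`` maps ModelParams field names to normal sd's applied around
    the archetype means (values truncated to stay physical).
    """

    name: str
    layer_label: str
    params: ModelParams
    jitter: dict[str, float] = field(default_factory=dict)
    cell_class: str = "pyramidal"  # pyramidal | putative_interneuron
    bursting: bool = False


def default_layer_archetypes() -> list[ArchetypeSpec]:
    """Per-layer pyramidal archetypes encoding the direction of the
    laminar contrasts: gh L5 > L3c > L2&3, L5 more depolarized EL, lower
    rheobase (higher input resistance), slower membrane time constant."""
    jit = {"C": 12.0, "gL": 0.8, "EL": 1.5, "gh": 0.4}
    return [
        ArchetypeSpec(
            "L23_pyr", "L2&3",
            ModelParams(C=165.0, gL=12.0, EL=-72.0, gh=1.5),
            jitter=jit,
        ),
        ArchetypeSpec(
            "L3c_pyr", "L3c",
            ModelParams(C=215.0, gL=12.6, EL=-71.0, gh=3.0),
            jitter=jit,
        ),
        ArchetypeSpec(
            "L5_pyr", "L5",
            ModelParams(C=205.0, gL=10.6, EL=-70.0, gh=5.0),
            jitter=jit,
        ),
    ]


def classification_archetypes() -> list[ArchetypeSpec]:
    """Archetypes for the rule-based classifier: regular pyramids, bursting
    pyramids (AHP trough near the spike cut gives a rheobase doublet), and
    fast-spiking interneurons (narrow AP, deep AHP, high maximal rate)."""
    jit = {"C": 8.0, "gL": 0.5, "EL": 1.0, "gh": 0.3}
    return [
        ArchetypeSpec(
            "pyr_regular", "L2&3",
            ModelParams(C=180.0, gL=11.0, EL=-71.0, gh=2.0,
                        ap_half_width=1.8, ap_ahp=8.0, b=100.0),
            jitter=jit, cell_class="pyramidal", bursting=False,
        ),
        ArchetypeSpec(
            "pyr_bursting", "L5",
            ModelParams(C=200.0, gL=10.0, EL=-69.0, gh=4.0,
                        ap_half_width=1.6, ap_ahp=1.5, b=120.0, tau_w=200.0),
            jitter=jit, cell_class="pyramidal", bursting=True,
        ),
        ArchetypeSpec(
            "interneuron", "L5",
            ModelParams(C=90.0, gL=9.0, EL=-68.0, gh=1.0,
                        ap_half_width=0.6, ap_ahp=15.0, ap_updown_ratio=1.4,
                        ap_peak=30.0, a=0.5, b=120.0, tau_w=10.0),
            jitter=jit, cell_class="putative_interneuron", bursting=False,
        ),
    ]


@dataclass
class CohortCell:
    cell_id: str
    layer_label: str
    archetype: str
    cell_class: str
    bursting: bool
    params: ModelParams
    sweep_sets: dict[str, SweepSet] = field(default_factory=dict)


def _sample_params(arch: ArchetypeSpec, rng: np.random.Generator, seed: int) -> ModelParams:
    p = arch.params
    updates: dict[str, float] = {}
    for name, sd in arch.jitter.items():
        base = getattr(p, name)
        lo = 0.25 * abs(base) if name in ("C", "gL") else None
        val = base + rng.normal(0.0, sd)
        if name == "gh":
            val = max(0.0, val)
        elif lo is not None:
            val = max(lo, val)
        updates[name] = float(val)
    return replace(p, seed=int(seed), **updates)


ZAP_REST = 0.5  # s of rest recorded before and after the chirp


def _zap_command(zap: ZapProtocol, amplitude: float, fs: float) -> tuple[np.ndarray, float, float]:
    """ZAP command padded with rest so the response tail is in-record."""
    cmd, _ = make_zap(replace(zap, amplitude=amplitude, sampling_rate=fs))
    pad = np.zeros(int(round(ZAP_REST * fs)))
    full = np.concatenate([pad, cmd, pad])
    return full, ZAP_REST, ZAP_REST + zap.duration


def _find_subthreshold_zap_amplitude(
    p: ModelParams, zap: ZapProtocol, fs: float
) -> float:
    """Emulate the acquisition rule: largest tested ZAP amplitude that does
    not elicit spiking (coarse descending grid)."""
    v0, _ = _steady_state(p)
    headroom = max(2.0, p.spike_cut - 4.0 - v0)  # mV
    a_max = headroom * p.gL  # pA, ignores gating boost
    for frac in (1.0, 0.8, 0.6, 0.45, 0.3, 0.2, 0.1):
        amp = frac * a_max
        cmd, _, _ = _zap_command(zap, amp, fs)
        res = simulate(p, cmd, fs, protocol_id="zap_sub")
        if len(res.spike_times) == 0:
            return amp
    return 0.05 * a_max


def calibrate_noise_dc(
    p: ModelParams,
    noise: NoiseProtocol,
    fs: float,
    target_rate: float = 8.0,
    n_probe_trials: int = 3,
    dc_step: float = 20.0,
    max_iter: int = 40,
) -> float:
    """Emulate the acquisition rule for noise stimulation: add DC steps to
    the noisy input until the mean spike rate exceeds the target (> 5 Hz
    criterion, aimed a little above it)."""
    dc = 0.0
    for _ in range(max_iter):
        rates = []
        for t in range(n_probe_trials):
            stim = make_frozen_filtered_noise(replace(noise, dc_offset=dc), trial=t)
            res = simulate(p, stim, fs, seed=p.seed + 40_000 + t)
            rates.append(len(res.spike_times) / noise.duration)
        if np.mean(rates) >= target_rate:
            return float(dc)
        dc += dc_step
    return float(dc)


def zd_analogue_params(gh: float, noise_sd: float = 5.0) -> ModelParams:
    """Model for the in-silico Ih-blocker experiment (gh=0 emulates ZD7288).

    A non-adapting regular-spiking cell with HCN1-like depolarized
    activation (V50 −70 mV, k 4 mV, τ 80 ms), so the gating feedback is
    engaged at the inter-spike operating potential and its contribution to
    the low-frequency gain can be read out in isolation from
    spike-frequency adaptation.
    """
    return ModelParams(gh=gh, a=0.0, b=10.0, V50h=-70.0, kh=4.0, tau_h=80.0,
                       noise_sd=noise_sd)


def simulate_gain_profile(
    p: ModelParams,
    noise: NoiseProtocol,
    fs: float = 10_000.0,
    n_trials: int = 30,
    freqs: np.ndarray | None = None,
    seed_base: int = 1000,
    max_lag: float = 1.0,
):
    """Frequency-dependent gain of a simulated cell under frozen noise.

    Runs ``n_trials`` frozen-noise trials (independent intrinsic-noise
    seeds), detects spikes by overshoot, and feeds the correlation
    estimator. Returns a :class:`ephyskit.gain.GainProfile`.
    """
    from .gain import correlations, firing_rate_signal, frequency_dependent_gain

    s_list, r_list = [], []
    for t in range(n_trials):
        stim = make_frozen_filtered_noise(noise, trial=t)
        res = simulate(p, stim, fs, seed=seed_base + t)
        idx = np.round(res.spike_times * fs).astype(int)
        s_list.append(stim - stim.mean())
        r_list.append(firing_rate_signal(idx, len(stim), fs))
    cp = correlations(s_list, r_list, max_lag=max_lag)
    return frequency_dependent_gain(cp, freqs)


def make_cohort(
    archetypes: Sequence[ArchetypeSpec] | None = None,
    n_per_archetype: int = 5,
    seed: int = 0,
    protocols: Sequence[str] = ("steps",),
    fs: float = 10_000.0,
    zap: ZapProtocol | None = None,
    noise: NoiseProtocol | None = None,
    step_range: tuple[float, float, float] = (-400.0, 400.0, 50.0),
    zap_trials_sub: int = 3,
    zap_trials_supra: int = 10,
) -> list[CohortCell]:
    """Sample cells from archetype distributions and run stimulus protocols.

    ``protocols`` selects which sweep sets to generate per cell:
    ``steps`` (current-clamp step family), ``zap_sub``, ``zap_supra``,
    ``noise`` (frozen filtered noise trials), ``vclamp`` (voltage steps
    −60 to −140 mV). Reproducible for a fixed seed.
    """
    archetypes = list(archetypes) if archetypes is not None else default_layer_archetypes()
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    zap = zap or ZapProtocol(sampling_rate=fs)
    noise = noise or NoiseProtocol(sampling_rate=fs)
    root = np.random.SeedSequence(int(seed) % 2**31)
    cells: list[CohortCell] = []
    for a_idx, arch in enumerate(archetypes):
        for k in range(n_per_archetype):
            ss = np.random.SeedSequence([int(seed) % 2**31, a_idx, k])
            rng = np.random.default_rng(ss)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            p = _sample_params(arch, rng, cell_seed)
            cid = f"{arch.name}_{k:03d}"
            cell = CohortCell(cid, arch.layer_label, arch.name,
                              arch.cell_class, arch.bursting, p)
            if "steps" in protocols:
                cmds = make_current_steps(*step_range, fs=fs, cell_id=cid)
                sweeps, amps = [], []
                for cmd_sweep, amp in zip(cmds.sweeps, cmds.amplitudes):
                    res = simulate(
                        p, cmd_sweep.current, fs, cell_id=cid,
                        layer_label=arch.layer_label, protocol_id="steps",
                        stim_onset=cmd_sweep.stim_onset,
                        stim_offset=cmd_sweep.stim_offset,
                        seed=cell_seed + 7919 * int(round(amp)) % 2**20,
                    )
                    sweeps.append(res.sweep)
                    amps.append(amp)
                cell.sweep_sets["steps"] = SweepSet(sweeps, amps)
            if "zap_sub" in protocols:
                amp = _find_subthreshold_zap_amplitude(p, zap, fs)
                cmd, on, off = _zap_command(zap, amp, fs)
                sweeps = []
                for t in range(zap_trials_sub):
                    res = simulate(p, cmd, fs, cell_id=cid,
                                   layer_label=arch.layer_label,
                                   protocol_id="zap_sub", stim_onset=on,
                                   stim_offset=off, seed=cell_seed + 100 + t)
                    sweeps.append(res.sweep)
                cell.sweep_sets["zap_sub"] = SweepSet(sweeps, [amp] * zap_trials_sub)
            if "zap_supra" in protocols:
                amp = _find_subthreshold_zap_amplitude(p, zap, fs) * 1.6
                cmd, on, off = _zap_command(zap, amp, fs)
                sweeps = []
                for t in range(zap_trials_supra):
                    res = simulate(p, cmd, fs, cell_id=cid,
                                   layer_label=arch.layer_label,
                                   protocol_id="zap_supra", stim_onset=on,
                                   stim_offset=off, seed=cell_seed + 500 + t)
                    sweeps.append(res.sweep)
                cell.sweep_sets["zap_supra"] = SweepSet(sweeps, [amp] * zap_trials_supra)
            if "noise" in protocols:
                dc = calibrate_noise_dc(p, noise, fs)
                cal = replace(noise, dc_offset=dc)
                sweeps = []
                for t in range(cal.n_trials):
                    stim = make_frozen_filtered_noise(cal, trial=t)
                    res = simulate(p, stim, fs, cell_id=cid,
                                   layer_label=arch.layer_label,
                                   protocol_id="noise", seed=cell_seed + 900 + t)
                    sweeps.append(res.sweep)
                cell.sweep_sets["noise"] = SweepSet(sweeps, [cal.noise_sd] * cal.n_trials)
            if "vclamp" in protocols:
                p_nospike = replace(p, spike_mechanism="none")
                sweeps, amps = [], []
                for v_step in np.arange(-60.0, -150.0, -10.0):
                    cmd = np.full(int(round(1.1 * fs)), -60.0)
                    on, off = int(round(0.2 * fs)), int(round(0.8 * fs))
                    cmd[on:off] = v_step
                    sw = simulate_vclamp(p_nospike, cmd, fs, cell_id=cid,
                                         stim_onset=on / fs, stim_offset=off / fs)
                    sweeps.append(sw)
                    amps.append(float(v_step))
                cell.sweep_sets["vclamp"] = SweepSet(sweeps, amps)
            cells.append(cell)
    return cells


def write_cohort(cells: Sequence[CohortCell], out_dir) -> "Path":
    """Write a cohort as canonical sweep manifests plus a labels CSV."""
    from pathlib import Path
    import csv as _csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .io import write_sweep_table

    with open(out / "labels.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["cell_id", "layer", "archetype", "cell_class", "bursting",
                    "gh_ns", "gl_ns", "c_pf", "el_mv", "seed"])
        for cell in cells:
            for proto, sset in cell.sweep_sets.items():
                write_sweep_table(sset, out / cell.cell_id / proto)
            w.writerow([cell.cell_id, cell.layer_label, cell.archetype,
                        cell.cell_class, int(cell.bursting),
                        repr(cell.params.gh), repr(cell.params.gL),
                        repr(cell.params.C), repr(cell.params.EL),
                        cell.params.seed])
    return out / "labels.csv"
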