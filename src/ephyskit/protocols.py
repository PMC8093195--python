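"""Stimulus waveform generators.

All analyses — on recorded or simulated data — share these generators as
the single source of truth for the three stimulus families:

* rectangular current steps (600 ms, −400 to +400 pA in 50-pA increments),
* a 20-s linear ZAP/chirp current sweeping 1→20 Hz, and
* 2.5-s frozen Gaussian white noise convolved with a 3-ms boxcar.

Generators are pure functions of their parameters (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SweepRecord, SweepSet

__all__ = [
    "ZapProtocol",
    "NoiseProtocol",
    "make_current_steps",
    "step_command",
    "make_zap",
    "zap_instantaneous_frequency",
    "make_frozen_filtered_noise",
]


@dataclass
class ZapProtocol:
    """Linear chirp: I(t) = A sin(2π [f0 t + (f1−f0) t² / (2T)])."""

    f0: float = 1.0  # Hz
    f1: float = 20.0  # Hz
    duration: float = 20.0  # s
    amplitude: float = 40.0  # pA
    sampling_rate: float = 10_000.0  # Hz
    sweep_mode: str = "linear"  # linear | exponential

    def __post_init__(self) -> None:
        if not (0 < self.f0 < self.f1):
            raise ValueError("require 0 < f0 < f1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sweep_mode not in ("linear", "exponential"):
            raise ValueError("sweep_mode must be 'linear' or 'exponential'")


@dataclass
class NoiseProtocol:
    """Frozen filtered Gaussian noise: white noise of sd ``noise_sd``
    convolved with a unit-sum boxcar of width ``box_width``, plus a DC
    offset. 'Frozen' means identical output for identical seed."""

    duration: float = 2.5  # s
    sampling_rate: float = 10_000.0  # Hz
    box_width: float = 0.003  # s
    noise_sd: float = 500.0  # pA (pre-filter; ~91 pA sd after the 3-ms boxcar)
    dc_offset: float = 0.0  # pA
    seed: int = 0
    n_trials: int = 30

    def __post_init__(self) -> None:
        if self.box_width <= 0 or self.duration <= 0:
            raise ValueError("box_width and duration must be > 0")


def step_command(
    amplitude: float, duration: float, pre: float, post: float, fs: float
) -> np.ndarray:
    """One rectangular current step (pA) with pre/post zero padding."""
    n_pre, n_dur, n_post = (int(round(t * fs)) for t in (pre, duration, post))
    out = np.zeros(n_pre + n_dur + n_post)
    out[n_pre : n_pre + n_dur] = amplitude
    return out


def make_current_steps(
    start: float,
    stop: float,
    increment: float,
    duration: float = 0.6,
    pre: float = 0.1,
    post: float = 0.3,
    fs: float = 10_000.0,
    cell_id: str = "command",
) -> SweepSet:
    """Family of rectangular step commands, one sweep per amplitude.

    The returned SweepSet holds the command in the ``current`` series
    (voltage is a zero placeholder) with stimulus epochs annotated.
    """
    if increment == 0:
        raise ValueError("increment must be nonzero")
    n_steps = (stop - start) / increment
    if abs(n_steps - round(n_steps)) > 1e-9:
        achievable = start + increment * np.arange(int(np.floor(n_steps)) + 1)
        raise ValueError(
            f"(stop - start) not divisible by increment; achievable amplitudes: "
            f"{list(achievable)}"
        )
    amplitudes = start + increment * np.arange(int(round(n_steps)) + 1)
    sweeps = []
    for amp in amplitudes:
        cmd = step_command(amp, duration, pre, post, fs)
        sweeps.append(
            SweepRecord(
                cell_id=cell_id,
                voltage=np.zeros_like(cmd),
                current=cmd,
                sampling_rate=fs,
                clamp_mode="current",
                protocol_id="steps",
                stim_onset=pre,
                stim_offset=pre + duration,
            )
        )
    return SweepSet(sweeps, [float(a) for a in amplitudes])


def zap_instantaneous_frequency(p: ZapProtocol) -> np.ndarray:
    """Instantaneous frequency (Hz) at each sample."""
    t = np.arange(int(round(p.duration * p.sampling_rate))) / p.sampling_rate
    if p.sweep_mode == "linear":
        return p.f0 + (p.f1 - p.f0) * t / p.duration
    return p.f0 * (p.f1 / p.f0) ** (t / p.duration)


def make_zap(p: ZapProtocol) -> tuple[np.ndarray, np.ndarray]:
    """ZAP current (pA) and its instantaneous frequency (Hz).

    Linear mode: I(t) = A sin(2π [f0 t + (f1−f0) t²/(2T)]), zero initial
    phase, constant amplitude.
    """
    if p.sampling_rate < 2 * p.f1:
        raise ValueError(
            f"sampling rate {p.sampling_rate} Hz aliases the {p.f1} Hz end frequency"
        )
    n = int(round(p.duration * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate
    if p.sweep_mode == "linear":
        phase = 2 * np.pi * (p.f0 * t + (p.f1 - p.f0) * t**2 / (2 * p.duration))
    else:
        k = np.log(p.f1 / p.f0) / p.duration
        phase = 2 * np.pi * p.f0 * (np.exp(k * t) - 1) / k
    return p.amplitude * np.sin(phase), zap_instantaneous_frequency(p)


def make_frozen_filtered_noise(p: NoiseProtocol, trial: int = 0) -> np.ndarray:
    """One trial of frozen filtered noise (pA).

    The boxcar kernel is normalized to unit sum, so ``noise_sd`` is the
    pre-filter white-noise sd; the post-filter sd is noise_sd / sqrt(M)
    with M the kernel length in samples. ``trial`` selects an independent
    frozen realization from the same seed stream.
    """
    n = int(round(p.duration * p.sampling_rate))
    m = max(1, int(round(p.box_width * p.sampling_rate)))
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed) % 2**31, int(trial)]))
    white = rng.normal(0.0, p.noise_sd, n + m - 1)
    kernel = np.ones(m) / m
    filtered = np.convolve(white, kernel, mode="valid")
    return filtered + p.dc_offset
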