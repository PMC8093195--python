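"""Spike detection, single-AP and spike-train features, cell classification.

Two detection modes: *overshoot* (voltage peaks above 0 mV separated by a
refractory margin — the mode used for all gain/resonance analyses) and
*dvdt* (threshold crossings of dV/dt rising toward a peak).

Single-AP features come from the first spike of the rheobase sweep; train
statistics from the "hero" sweep, the sweep 39–61 pA above rheobase.
Rule-based classification: bursting iff the instantaneous frequency of
the first inter-spike interval at rheobase exceeds 75 Hz; putative
interneuron iff spike half-width < 1 ms, AHP amplitude > 10 mV and the
maximal firing rate over the step family exceeds 75 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import SweepRecord, SweepSet

__all__ = [
    "SpikeTrain",
    "APWaveformFeatures",
    "TrainFeatures",
    "detect_spikes",
    "ap_waveform_features",
    "train_features",
    "classify_cell",
    "Classification",
]

DVDT_THRESHOLD = 20.0  # mV/ms, AP threshold criterion
REFRACTORY = 0.002  # s, minimum peak separation (overshoot mode)
BURST_RATE = 75.0  # Hz, instantaneous-frequency criterion
HERO_WINDOW = (39.0, 61.0)  # pA above rheobase


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # s, strictly increasing
    spike_indices: np.ndarray
    detection_mode: str
    sweep: SweepRecord

    def __post_init__(self) -> None:
        if len(self.spike_times) > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)

    @property
    def isis_ms(self) -> np.ndarray:
        return np.diff(self.spike_times) * 1e3


@dataclass
class APWaveformFeatures:
    threshold: float  # mV
    peak: float  # mV
    amplitude: float  # mV (= peak - threshold)
    half_width: float  # ms
    upstroke_downstroke_ratio: float
    ahp_amplitude: float  # mV (threshold - post-spike trough)
    latency: float  # ms, stimulus onset -> first spike
    rheobase_sweep_amplitude: float = float("nan")


@dataclass
class TrainFeatures:
    rheobase: float  # pA
    fi_slope: float  # Hz/pA
    adaptation_index: float
    isi_first: float  # ms
    isi_mean: float  # ms
    isi_median: float  # ms
    isi_cv: float
    avg_rate_hero: float  # Hz
    hero_amplitude: float  # pA
    isi_first_rheobase: float  # ms (bursting criterion input)
    isi_first_rheo_plus50: float  # ms
    max_rate: float  # Hz over the step family
    hero_flagged: bool = False


@dataclass
class Classification:
    cell_class: str  # pyramidal | putative_interneuron
    bursting: str  # none | at_rheobase | at_rheobase_plus_50


def detect_spikes(
    sweep: SweepRecord,
    mode: str = "overshoot",
    dvdt_threshold: float = DVDT_THRESHOLD,
    refractory: float = REFRACTORY,
) -> SpikeTrain:
    """Detect action potentials in a current-clamp sweep.

    overshoot: local voltage maxima above 0 mV, separated by at least the
    refractory margin. dvdt: upward crossings of ``dvdt_threshold``
    (mV/ms), each assigned to the following voltage peak.
    """
    if sweep.clamp_mode != "current":
        raise ValueError("spike detection requires a current-clamp sweep")
    fs = sweep.sampling_rate
    v = sweep.voltage
    distance = max(1, int(round(refractory * fs)))
    if mode == "overshoot":
        idx, _ = find_peaks(v, height=0.0, distance=distance)
    elif mode == "dvdt":
        dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
        crossings = np.flatnonzero((dvdt[:-1] < dvdt_threshold) & (dvdt[1:] >= dvdt_threshold)) + 1
        peaks, _ = find_peaks(v, distance=distance)
        idx = []
        for c in crossings:
            later = peaks[peaks >= c]
            if later.size:
                k = int(later[0])
                if not idx or k - idx[-1] >= distance:
                    idx.append(k)
        idx = np.asarray(idx, dtype=int)
    else:
        raise ValueError("mode must be 'overshoot' or 'dvdt'")
    idx = np.asarray(idx, dtype=int)
    return SpikeTrain(idx / fs, idx, mode, sweep)


def _spike_threshold_index(
    v: np.ndarray, peak_idx: int, fs: float, dvdt_threshold: float
) -> int:
    """Walk back from the peak to the first sample where dV/dt rises
    through the threshold criterion."""
    dvdt = np.gradient(v) * fs / 1000.0
    k = peak_idx
    lo = max(0, peak_idx - int(0.01 * fs))
    while k > lo and dvdt[k - 1] >= dvdt_threshold:
        k -= 1
    return k


def ap_waveform_features(
    sweeps: SweepSet,
    mode: str = "overshoot",
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> APWaveformFeatures:
    """Single-AP features from the first spike of the rheobase sweep."""
    rheo = _rheobase_sweep(sweeps, mode)
    if rheo is None:
        raise ValueError("no suprathreshold sweep in the set")
    sweep, amp, train = rheo
    fs = sweep.sampling_rate
    v = sweep.voltage
    p0 = int(train.spike_indices[0])
    thr_idx = _spike_threshold_index(v, p0, fs, dvdt_threshold)
    threshold = float(v[thr_idx])
    peak = float(v[p0])
    amplitude = peak - threshold
    # half-width at threshold + amplitude/2
    half_level = threshold + amplitude / 2.0
    i = p0
    while i > thr_idx and v[i - 1] >= half_level:
        i -= 1
    j = p0
    end = train.spike_indices[1] if len(train) > 1 else len(v)
    while j < end - 1 and v[j + 1] >= half_level:
        j += 1
    # linear interpolation at both crossings
    t_left = i - (v[i] - half_level) / max(v[i] - v[i - 1], 1e-12) if i > 0 else i
    t_right = j + (v[j] - half_level) / max(v[j] - v[j + 1], 1e-12) if j < len(v) - 1 else j
    half_width = float((t_right - t_left) / fs * 1e3)
    dvdt = np.gradient(v) * fs / 1000.0
    trough_end = int(min(end, p0 + int(0.05 * fs)))
    up = float(np.max(dvdt[thr_idx: p0 + 1]))
    down = float(np.min(dvdt[p0: trough_end])) if trough_end > p0 else float("nan")
    ud_ratio = up / abs(down) if down else float("nan")
    trough = float(np.min(v[p0:trough_end])) if trough_end > p0 else float("nan")
    ahp = threshold - trough
    latency = float((train.spike_times[0] - sweep.stim_onset) * 1e3)
    return APWaveformFeatures(
        threshold=threshold,
        peak=peak,
        amplitude=amplitude,
        half_width=half_width,
        upstroke_downstroke_ratio=ud_ratio,
        ahp_amplitude=ahp,
        latency=latency,
        rheobase_sweep_amplitude=amp,
    )


def _rheobase_sweep(sweeps: SweepSet, mode: str):
    """Smallest-amplitude suprathreshold sweep: (sweep, amplitude, train)."""
    best = None
    for sweep, amp in zip(sweeps.sweeps, sweeps.amplitudes):
        if amp <= 0:
            continue
        train = detect_spikes(sweep, mode)
        if len(train) >= 1 and (best is None or amp < best[1]):
            best = (sweep, amp, train)
    return best


def _first_isi_ms(sweeps: SweepSet, amplitude: float, mode: str) -> float:
    try:
        sweep = sweeps.sweep_at(amplitude)
    except KeyError:
        return float("nan")
    train = detect_spikes(sweep, mode)
    return float(train.isis_ms[0]) if len(train) >= 2 else float("nan")


def train_features(sweeps: SweepSet, mode: str = "overshoot") -> TrainFeatures:
    """Spike-train features over a depolarizing step family.

    The firing rate per sweep is spike count divided by the stimulus
    duration; the f–I slope is the least-squares slope over sweeps at or
    above rheobase. The adaptation index is the mean over consecutive ISI
    pairs of (ISI_{i+1} − ISI_i)/(ISI_{i+1} + ISI_i) on the hero sweep.
    """
    rheo = _rheobase_sweep(sweeps, mode)
    if rheo is None:
        raise ValueError("no spiking sweep: train features undefined")
    _, rheobase, _ = rheo
    duration = None
    rates, amps = [], []
    counts = {}
    for sweep, amp in zip(sweeps.sweeps, sweeps.amplitudes):
        if amp < rheobase:
            continue
        train = detect_spikes(sweep, mode)
        dur = sweep.stim_offset - sweep.stim_onset
        duration = duration or dur
        in_step = np.sum(
            (train.spike_times >= sweep.stim_onset)
            & (train.spike_times < sweep.stim_offset)
        )
        rates.append(in_step / dur)
        amps.append(amp)
        counts[amp] = (sweep, train)
    fi_slope = (
        float(np.polyfit(np.asarray(amps), np.asarray(rates), 1)[0])
        if len(amps) >= 2
        else float("nan")
    )
    max_rate = float(np.max(rates))

    # hero sweep: closest to rheobase + 50 within [+39, +61]; ties -> smaller
    target = rheobase + 50.0
    window = [a for a in amps if HERO_WINDOW[0] <= a - rheobase <= HERO_WINDOW[1]]
    hero_flagged = False
    if window:
        hero_amp = min(window, key=lambda a: (abs(a - target), a))
    else:
        hero_flagged = True
        others = [a for a in amps if a > rheobase] or list(amps)
        hero_amp = min(others, key=lambda a: (abs(a - target), a))
        warnings.warn(
            f"no sweep within +{HERO_WINDOW[0]:.0f}..+{HERO_WINDOW[1]:.0f} pA of "
            f"rheobase; using {hero_amp:.0f} pA", stacklevel=2,
        )
    hero_sweep, hero_train = counts[hero_amp]
    isis = hero_train.isis_ms
    if len(isis) >= 2:
        pair = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
        adaptation = float(np.mean(pair))
    else:
        adaptation = float("nan")
    hero_dur = hero_sweep.stim_offset - hero_sweep.stim_onset
    in_hero = np.sum(
        (hero_train.spike_times >= hero_sweep.stim_onset)
        & (hero_train.spike_times < hero_sweep.stim_offset)
    )
    return TrainFeatures(
        rheobase=float(rheobase),
        fi_slope=fi_slope,
        adaptation_index=adaptation,
        isi_first=float(isis[0]) if isis.size else float("nan"),
        isi_mean=float(np.mean(isis)) if isis.size else float("nan"),
        isi_median=float(np.median(isis)) if isis.size else float("nan"),
        isi_cv=float(np.std(isis) / np.mean(isis)) if isis.size else float("nan"),
        avg_rate_hero=float(in_hero / hero_dur),
        hero_amplitude=float(hero_amp),
        isi_first_rheobase=_first_isi_ms(sweeps, rheobase, mode),
        isi_first_rheo_plus50=_first_isi_ms(sweeps, rheobase + 50.0, mode),
        max_rate=max_rate,
        hero_flagged=hero_flagged,
    )


def classify_cell(
    ap: APWaveformFeatures, train: TrainFeatures, max_rate: float | None = None
) -> Classification:
    """Rule-based bursting and interneuron labels.

    Bursting at rheobase iff 1000/first-ISI(rheobase) > 75 Hz; otherwise
    the same criterion is evaluated at rheobase + 50 pA. Putative
    interneuron iff half-width < 1 ms AND AHP > 10 mV AND maximal firing
    rate > 75 Hz.
    """
    rate = train.max_rate if max_rate is None else max_rate
    bursting = "none"
    if np.isfinite(train.isi_first_rheobase) and 1000.0 / train.isi_first_rheobase > BURST_RATE:
        bursting = "at_rheobase"
    elif (
        np.isfinite(train.isi_first_rheo_plus50)
        and 1000.0 / train.isi_first_rheo_plus50 > BURST_RATE
    ):
        bursting = "at_rheobase_plus_50"
    interneuron = (
        ap.half_width < 1.0 and ap.ahp_amplitude > 10.0 and rate > BURST_RATE
    )
    return Classification(
        cell_class="putative_interneuron" if interneuron else "pyramidal",
        bursting=bursting,
    )
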