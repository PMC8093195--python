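"""Subthreshold ZAP impedance and suprathreshold spike-probability density.

The impedance profile is the frequency-domain ratio of voltage over
current under a subthreshold ZAP stimulus: Z(f) = V̂(f)/Î(f) over the
stimulus band, magnitude in MΩ, smoothed by a centered moving average.
The resonance (center) frequency fR is the argmax of the smoothed |Z|;
the cutoff frequency is where |Z| first falls to a configured fraction
of |Z(fR)| above fR; a cell is *resonant* when fR exceeds 0.5 Hz and the
peak is interior to the evaluated band.

Under a suprathreshold ZAP each spike is assigned the instantaneous
stimulus frequency at its time; pooled frequencies over trials form the
spike-probability density, compared between groups with a two-sample
Kolmogorov–Smirnov test on the per-spike samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import ks_2samp

from .io import SweepSet
from .protocols import ZapProtocol, zap_instantaneous_frequency
from .spikes import detect_spikes

__all__ = [
    "ImpedanceProfile",
    "SpikeFrequencyDensity",
    "impedance_profile",
    "spike_probability_density",
    "compare_densities",
]

SMOOTH_WIDTH_HZ = 0.5  # moving-average width over the |Z| grid
CUTOFF_FRACTION = 1.0 / np.sqrt(2.0)  # 3 dB amplitude point (0.5 also offered)
RESONANT_MIN_FR = 0.5  # Hz
MAX_TRIALS = 5


@dataclass
class ImpedanceProfile:
    freqs: np.ndarray  # Hz
    z_mag: np.ndarray  # MΩ, smoothed
    z_mag_norm: np.ndarray  # max 1
    fR: float  # Hz
    f3db: float  # Hz (nan if |Z| never falls below the cutoff)
    resonant: bool
    n_trials_averaged: int


@dataclass
class SpikeFrequencyDensity:
    bin_edges: np.ndarray  # Hz
    probability: np.ndarray  # per bin, sums to 1 when spikes exist
    n_spikes_total: int
    spike_frequencies: np.ndarray  # per-spike samples, pooled over trials


def impedance_profile(
    trials: SweepSet,
    zap: ZapProtocol,
    smooth_width_hz: float = SMOOTH_WIDTH_HZ,
    cutoff_fraction: float = CUTOFF_FRACTION,
) -> ImpedanceProfile:
    """Impedance profile of one cell from up to five subthreshold ZAP trials.

    Spiking trials are rejected with a warning; the voltage is averaged
    across the remaining trials before the Fourier ratio is taken.
    """
    clean = []
    for sweep in trials:
        if len(detect_spikes(sweep, mode="overshoot")) > 0:
            warnings.warn(
                f"trial with spikes excluded from impedance averaging "
                f"(cell {sweep.cell_id})", stacklevel=2,
            )
            continue
        clean.append(sweep)
        if len(clean) == MAX_TRIALS:
            break
    if not clean:
        raise ValueError("all ZAP trials contain spikes; impedance undefined")
    fs = clean[0].sampling_rate
    n = min(s.n_samples for s in clean)
    v_mean = np.mean([s.voltage[:n] for s in clean], axis=0)
    current = clean[0].current[:n]

    v_hat = np.fft.rfft(v_mean - v_mean.mean())
    i_hat = np.fft.rfft(current - current.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= zap.f0) & (freqs <= zap.f1)
    freqs_b = freqs[band]
    z_raw = np.abs(v_hat[band] / i_hat[band]) * 1e3  # mV/pA = GΩ -> MΩ

    df = freqs[1] - freqs[0]
    width = max(1, int(round(smooth_width_hz / df)))
    if width % 2 == 0:
        width += 1
    z_smooth = uniform_filter1d(z_raw, size=width, mode="nearest")

    search = freqs_b >= RESONANT_MIN_FR
    idx_search = np.flatnonzero(search)
    k = idx_search[np.argmax(z_smooth[idx_search])]
    fR = float(freqs_b[k])
    interior = k > idx_search[0]
    resonant = bool(fR > RESONANT_MIN_FR and interior)

    above = z_smooth[k:]
    below = np.flatnonzero(above <= cutoff_fraction * z_smooth[k])
    f3db = float(freqs_b[k + below[0]]) if below.size else float("nan")

    return ImpedanceProfile(
        freqs=freqs_b,
        z_mag=z_smooth,
        z_mag_norm=z_smooth / z_smooth.max(),
        fR=fR,
        f3db=f3db,
        resonant=resonant,
        n_trials_averaged=len(clean),
    )


def spike_probability_density(
    trials: SweepSet,
    zap: ZapProtocol,
    bin_width_hz: float = 1.0,
) -> SpikeFrequencyDensity:
    """Spike-probability density over instantaneous stimulus frequency.

    Each spike (overshoot detection) is assigned the ZAP instantaneous
    frequency at its time; frequencies pooled over trials are binned and
    normalized by the total spike count.
    """
    inst_freq = zap_instantaneous_frequency(zap)
    samples = []
    for sweep in trials:
        fs = sweep.sampling_rate
        offset = sweep.sample_of(sweep.stim_onset)
        train = detect_spikes(sweep, mode="overshoot")
        for idx in train.spike_indices:
            k = int(np.clip(int(idx) - offset, 0, len(inst_freq) - 1))
            samples.append(inst_freq[k])
    samples = np.asarray(samples, dtype=float)
    edges = np.arange(zap.f0, zap.f1 + bin_width_hz, bin_width_hz)
    if samples.size == 0:
        warnings.warn("no spikes in any trial; empty density", stacklevel=2)
        prob = np.zeros(len(edges) - 1)
    else:
        counts, _ = np.histogram(samples, bins=edges)
        prob = counts / samples.size
    return SpikeFrequencyDensity(
        bin_edges=edges,
        probability=prob,
        n_spikes_total=int(samples.size),
        spike_frequencies=samples,
    )


def compare_densities(
    a: SpikeFrequencyDensity,
    b: SpikeFrequencyDensity,
    band: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Two-sample KS test on the pooled per-spike frequency samples.

    ``band`` optionally restricts both samples to a frequency range
    (e.g. > 12 Hz) before the comparison.
    """
    xa, xb = a.spike_frequencies, b.spike_frequencies
    if band is not None:
        lo, hi = band
        xa = xa[(xa >= lo) & (xa <= hi)]
        xb = xb[(xb >= lo) & (xb <= hi)]
    if xa.size == 0 or xb.size == 0:
        raise ValueError("empty sample set after band restriction")
    res = ks_2samp(xa, xb)
    return float(res.statistic), float(res.pvalue)
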