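"""Sweep data model and plain-text sweep I/O.

A *sweep* is one paired voltage/current acquisition from a whole-cell
recording (or a simulation emulating one): voltage in mV, current in pA
(current clamp) or command voltage in mV (voltage clamp), sampled at a
fixed rate, with the stimulus epoch annotated.

On-disk format (canonical, diffable, language-neutral): one text file per
sweep with a ``# key: value`` header block followed by two whitespace
separated data columns (voltage_mV, current_pA), plus a per-cell manifest
CSV listing (sweep_file, protocol_id, amplitude).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SweepRecord",
    "SweepSet",
    "SweepFormatError",
    "EpochDetection",
    "read_sweep_table",
    "write_sweep_table",
    "read_sweep_file",
    "write_sweep_file",
    "detect_stimulus_epoch",
    "read_nwb_sweeps",
]

LAYER_LABELS = ("L2&3", "L3c", "L5", "unknown")
CLAMP_MODES = ("current", "voltage")


class SweepFormatError(ValueError):
    """Raised when a sweep file or manifest violates the documented format."""


@dataclass
class SweepRecord:
    """One paired voltage/current time series with stimulus annotations.

    Attributes
    ----------
    voltage : ndarray
        Membrane (or command, in voltage clamp this is the *response*
        current holder's counterpart) potential in mV.
    current : ndarray
        Injected current in pA (current clamp) or command potential in mV
        (voltage clamp).
    sampling_rate : float
        Samples per second (Hz).
    stim_onset, stim_offset : float
        Stimulus epoch in seconds from sweep start.
    """

    cell_id: str
    voltage: np.ndarray
    current: np.ndarray
    sampling_rate: float
    clamp_mode: str = "current"
    layer_label: str = "unknown"
    protocol_id: str = ""
    stim_onset: float = 0.0
    stim_offset: float = 0.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.ndim != 1 or self.current.ndim != 1:
            raise SweepFormatError("voltage and current must be 1-D series")
        if len(self.voltage) != len(self.current):
            raise SweepFormatError(
                f"voltage length {len(self.voltage)} != current length "
                f"{len(self.current)}"
            )
        if len(self.voltage) < 2:
            raise SweepFormatError("sweep must contain at least 2 samples")
        if not self.sampling_rate > 0:
            raise SweepFormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.clamp_mode not in CLAMP_MODES:
            raise SweepFormatError(f"clamp_mode must be one of {CLAMP_MODES}")
        if self.layer_label not in LAYER_LABELS:
            raise SweepFormatError(f"layer_label must be one of {LAYER_LABELS}")
        if not (0.0 <= self.stim_onset <= self.stim_offset <= self.duration + 1e-12):
            raise SweepFormatError(
                f"stimulus epoch [{self.stim_onset}, {self.stim_offset}] outside "
                f"sweep duration {self.duration}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.voltage)

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time base in seconds, implicit from the sampling rate."""
        return np.arange(len(self.voltage)) / self.sampling_rate

    def sample_of(self, t: float) -> int:
        return int(round(t * self.sampling_rate))

    def with_series(self, voltage=None, current=None) -> "SweepRecord":
        return replace(
            self,
            voltage=self.voltage if voltage is None else voltage,
            current=self.current if current is None else current,
        )


@dataclass
class SweepSet:
    """Ordered collection of sweeps from one cell and one protocol.

    All members share the sampling rate and clamp mode; ``amplitudes``
    records the per-sweep stimulus amplitude (pA, or mV in voltage clamp).
    """

    sweeps: list[SweepRecord]
    amplitudes: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.amplitudes:
            self.amplitudes = [0.0] * len(self.sweeps)
        if len(self.amplitudes) != len(self.sweeps):
            raise SweepFormatError("one amplitude per sweep required")
        if self.sweeps:
            cid = {s.cell_id for s in self.sweeps}
            if len(cid) > 1:
                raise SweepFormatError(f"sweeps from multiple cells in one set: {sorted(cid)}")
            if len({s.protocol_id for s in self.sweeps}) > 1:
                raise SweepFormatError("sweeps from multiple protocols in one set")
            if len({s.sampling_rate for s in self.sweeps}) > 1:
                raise SweepFormatError("sweeps with differing sampling rates in one set")
            if len({s.clamp_mode for s in self.sweeps}) > 1:
                raise SweepFormatError("sweeps with differing clamp modes in one set")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self) -> Iterator[SweepRecord]:
        return iter(self.sweeps)

    def __getitem__(self, i) -> SweepRecord:
        return self.sweeps[i]

    @property
    def cell_id(self) -> str:
        return self.sweeps[0].cell_id if self.sweeps else ""

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate if self.sweeps else float("nan")

    @property
    def clamp_mode(self) -> str:
        return self.sweeps[0].clamp_mode if self.sweeps else "current"

    def sweep_at(self, amplitude: float, atol: float = 1e-6) -> SweepRecord:
        for s, a in zip(self.sweeps, self.amplitudes):
            if abs(a - amplitude) <= atol:
                return s
        raise KeyError(f"no sweep with amplitude {amplitude}")


# ---------------------------------------------------------------------------
# text format

_HEADER_FLOAT = ("sampling_rate_hz", "stim_onset_s", "stim_offset_s", "amplitude")


def write_sweep_file(sweep: SweepRecord, path: Path, amplitude: float = 0.0) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# cell_id: {sweep.cell_id}\n")
        fh.write(f"# layer: {sweep.layer_label}\n")
        fh.write(f"# protocol_id: {sweep.protocol_id}\n")
        fh.write(f"# clamp_mode: {sweep.clamp_mode}\n")
        fh.write(f"# sampling_rate_hz: {float(sweep.sampling_rate)!r}\n")
        fh.write(f"# stim_onset_s: {float(sweep.stim_onset)!r}\n")
        fh.write(f"# stim_offset_s: {float(sweep.stim_offset)!r}\n")
        fh.write(f"# amplitude: {float(amplitude)!r}\n")
        fh.write("voltage_mV\tcurrent_pA\n")
        for v, i in zip(sweep.voltage.tolist(), sweep.current.tolist()):
            fh.write(f"{v!r}\t{i!r}\n")
    return path


def read_sweep_file(path: Path) -> tuple[SweepRecord, float]:
    """Read one sweep file; returns (sweep, stimulus amplitude)."""
    path = Path(path)
    header: dict[str, str] = {}
    volts: list[float] = []
    amps: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise SweepFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = line.lstrip("# ").partition(":")
                header[key.strip()] = val.strip()
            elif line.startswith("voltage_mV"):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise SweepFormatError(
                        f"{path}:{lineno}: expected 2 data columns, got {len(parts)}"
                    )
                volts.append(float(parts[0]))
                amps.append(float(parts[1]))
    for key in ("cell_id", "clamp_mode", "sampling_rate_hz"):
        if key not in header:
            raise SweepFormatError(f"{path}: missing required header field '{key}'")
    vals = {}
    for key in _HEADER_FLOAT:
        if key in header:
            try:
                vals[key] = float(header[key])
            except ValueError as exc:
                raise SweepFormatError(f"{path}: field '{key}' is not numeric") from exc
    sweep = SweepRecord(
        cell_id=header["cell_id"],
        layer_label=header.get("layer", "unknown"),
        protocol_id=header.get("protocol_id", ""),
        clamp_mode=header["clamp_mode"],
        sampling_rate=vals["sampling_rate_hz"],
        stim_onset=vals.get("stim_onset_s", 0.0),
        stim_offset=vals.get("stim_offset_s", 0.0),
        voltage=np.array(volts),
        current=np.array(amps),
    )
    return sweep, vals.get("amplitude", 0.0)


def write_sweep_table(sweeps: SweepSet, path: Path) -> Path:
    """Write a SweepSet as one directory: per-sweep text files + manifest.csv.

    ``path`` may be a directory or a ``manifest.csv`` path inside one.
    Returns the manifest path, re-readable by :func:`read_sweep_table`.
    """
    path = Path(path)
    if path.suffix == ".csv":
        manifest, folder = path, path.parent
    else:
        folder, manifest = path, path / "manifest.csv"
    folder.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (sweep, amp) in enumerate(zip(sweeps.sweeps, sweeps.amplitudes)):
        name = f"sweep_{k:03d}.txt"
        write_sweep_file(sweep, folder / name, amplitude=amp)
        rows.append((name, sweep.protocol_id, repr(float(amp))))
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sweep_file", "protocol_id", "amplitude"])
        w.writerows(rows)
    return manifest


def read_sweep_table(path: Path) -> SweepSet:
    """Read a manifest (or its directory) back into a SweepSet."""
    path = Path(path)
    manifest = path / "manifest.csv" if path.is_dir() else path
    if not manifest.exists():
        raise SweepFormatError(f"manifest not found: {manifest}")
    sweeps: list[SweepRecord] = []
    amps: list[float] = []
    with open(manifest) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sweep_file" not in reader.fieldnames:
            raise SweepFormatError(f"{manifest}: missing 'sweep_file' column")
        for row in reader:
            sweep, amp = read_sweep_file(manifest.parent / row["sweep_file"])
            if row.get("amplitude"):
                amp = float(row["amplitude"])
            sweeps.append(sweep)
            amps.append(amp)
    return SweepSet(sweeps, amps)


# ---------------------------------------------------------------------------
# stimulus epoch detection

@dataclass
class EpochDetection:
    stim_onset: float
    stim_offset: float
    amplitude: float
    found: bool


def detect_stimulus_epoch(
    sweep: SweepRecord,
    threshold: float = 10.0,
    baseline_window: float = 0.05,
) -> EpochDetection:
    """Locate a single rectangular current step in a current-clamp sweep.

    Onset/offset are the first/last samples where the current deviates from
    the pre-stimulus baseline by more than ``threshold`` (pA); amplitude is
    the median in-step current minus baseline. A flat sweep returns a
    flagged zero-amplitude epoch.
    """
    if sweep.clamp_mode != "current":
        raise ValueError("stimulus epoch detection requires a current-clamp sweep")
    i = sweep.current
    nbase = max(1, sweep.sample_of(baseline_window))
    base = float(np.median(i[:nbase]))
    dev = np.abs(i - base) > threshold
    if not dev.any():
        return EpochDetection(0.0, 0.0, 0.0, found=False)
    first = int(np.argmax(dev))
    last = int(len(dev) - np.argmax(dev[::-1]))  # one past the last deviating sample
    amp = float(np.median(i[first:last]) - base)
    fs = sweep.sampling_rate
    return EpochDetection(first / fs, last / fs, amp, found=True)


# ---------------------------------------------------------------------------
# optional NWB reader (feature-flagged; the text format is canonical)

def read_nwb_sweeps(path: Path, cell_id: str | None = None) -> SweepSet:
    """Read intracellular series from an NWB file (requires ``pynwb``).

    Optional: the canonical exchange format is the plain-text one above.
    """
    try:
        import pynwb  # noqa: F401
        from pynwb import NWBHDF5IO
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "NWB reading requires the optional 'pynwb' dependency "
            "(pip install ephyskit[nwb]); the plain-text sweep format does not."
        ) from exc
    from pynwb.icephys import CurrentClampSeries, VoltageClampSeries  # pragma: no cover

    sweeps: list[SweepRecord] = []  # pragma: no cover
    with NWBHDF5IO(str(path), "r") as io:  # pragma: no cover
        nwb = io.read()
        for obj in nwb.acquisition.values():
            if isinstance(obj, (CurrentClampSeries, VoltageClampSeries)):
                data = np.asarray(obj.data[:], dtype=float)
                fs = float(obj.rate) if obj.rate else 1.0 / float(obj.timestamps[1] - obj.timestamps[0])
                mode = "current" if isinstance(obj, CurrentClampSeries) else "voltage"
                scale = 1e3 if mode == "current" else 1e12
                sweeps.append(
                    SweepRecord(
                        cell_id=cell_id or (nwb.identifier or "nwb"),
                        voltage=data * scale if mode == "current" else np.zeros_like(data),
                        current=np.zeros_like(data) if mode == "current" else data * scale,
                        sampling_rate=fs,
                        clamp_mode=mode,
                        protocol_id=obj.name,
                        stim_offset=len(data) / fs,
                    )
                )
    return SweepSet(sweeps)  # pragma: no cover
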