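"""One-command orchestration: sweep manifests -> cohort report bundle.

A cohort directory holds one subdirectory per cell with one manifest per
protocol (``steps``, ``zap_sub``, ``zap_supra``, ``noise``, ``vclamp``),
as written by :func:`ephyskit.sim.write_cohort` or produced by an
acquisition export. ``run_cohort_analysis`` extracts every feature the
relevant protocols support, per cell, with per-cell error isolation
(a failing cell is reported and skipped, the run continues), and writes:

* ``features.csv`` — the 14-feature vector + classification per cell,
* ``impedance.csv`` / ``gain.csv`` / ``vclamp.csv`` — per-cell profiles,
* ``embedding.csv`` — 2-D UMAP coordinates (when enough cells),
* ``errors.csv`` — per-cell error summary,
* ``provenance.json`` — parameters, seed, package version.

Reruns with an identical config and seed produce bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import assemble_feature_vector, cohort_table, embed_cohort
from .gain import correlations, firing_rate_signal, frequency_dependent_gain
from .io import SweepSet, read_sweep_table
from .passive import passive_features
from .protocols import ZapProtocol
from .resonance import impedance_profile, spike_probability_density
from .spikes import ap_waveform_features, classify_cell, detect_spikes, train_features
from .vclamp import activation_curve, ih_step_amplitudes

__all__ = ["RunConfig", "run_cohort_analysis"]

PROTOCOL_NAMES = ("steps", "zap_sub", "zap_supra", "noise", "vclamp")


@dataclass
class RunConfig:
    cohort_dir: Path
    out_dir: Path
    seed: int = 0
    zap: ZapProtocol = field(default_factory=ZapProtocol)
    embed: bool = True
    min_cells_for_embedding: int = 10
    gain_max_lag: float = 1.0

    @classmethod
    def from_toml(cls, path: Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        zap = ZapProtocol(**raw.pop("zap", {}))
        return cls(
            cohort_dir=Path(raw.pop("cohort_dir")),
            out_dir=Path(raw.pop("out_dir")),
            zap=zap,
            **raw,
        )


def _discover_cells(cohort_dir: Path) -> dict[str, dict[str, Path]]:
    cells: dict[str, dict[str, Path]] = {}
    for cell_dir in sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir()):
        protos = {
            name: cell_dir / name / "manifest.csv"
            for name in PROTOCOL_NAMES
            if (cell_dir / name / "manifest.csv").exists()
        }
        if protos:
            cells[cell_dir.name] = protos
    return cells


def _analyze_cell(cell_id: str, manifests: dict[str, Path], cfg: RunConfig):
    """Feature extraction for one cell; returns row dicts per output table."""
    out: dict[str, object] = {}
    sets: dict[str, SweepSet] = {
        name: read_sweep_table(path) for name, path in manifests.items()
    }
    ann = {}
    if "steps" in sets:
        steps = sets["steps"]
        ann["layer"] = steps[0].layer_label
        pf = passive_features(steps)
        try:
            ap = ap_waveform_features(steps)
            tf = train_features(steps)
            cls = classify_cell(ap, tf)
        except ValueError:
            ap = tf = cls = None
        vec = assemble_feature_vector(pf, ap, tf, cell_id=cell_id, annotations=ann)
        row = dict(vec.values)
        row["rebound_amplitude"] = pf.rebound_amplitude
        row["rebound_spike_count"] = pf.rebound_spike_count
        if tf is not None:
            row["adaptation_index"] = tf.adaptation_index
            row["isi_first"] = tf.isi_first
            row["isi_mean"] = tf.isi_mean
            row["isi_median"] = tf.isi_median
            row["isi_cv"] = tf.isi_cv
        if cls is not None:
            row["cell_class"] = cls.cell_class
            row["bursting"] = cls.bursting
        out["features"] = row
        out["vector"] = vec
    if "zap_sub" in sets:
        prof = impedance_profile(sets["zap_sub"], cfg.zap)
        out["impedance"] = {
            "fR_hz": prof.fR,
            "f3db_hz": prof.f3db,
            "resonant": prof.resonant,
            "z_max_mohm": float(prof.z_mag.max()),
            "n_trials": prof.n_trials_averaged,
        }
    if "zap_supra" in sets:
        dens = spike_probability_density(sets["zap_supra"], cfg.zap)
        out["spike_density"] = dens
    if "noise" in sets:
        trials = sets["noise"]
        fs = trials.sampling_rate
        s_list, r_list = [], []
        for sweep in trials:
            train = detect_spikes(sweep, mode="overshoot")
            s_list.append(sweep.current - np.mean(sweep.current))
            r_list.append(firing_rate_signal(train, sweep.n_samples, fs))
        cp = correlations(s_list, r_list, max_lag=cfg.gain_max_lag)
        gp = frequency_dependent_gain(cp)
        out["gain_profile"] = gp
        out["gain"] = {
            "mean_rate_hz": gp.mean_rate,
            "tau_delay_ms": gp.tau_delay * 1e3,
            "gain_5hz": float(np.interp(5.0, gp.freqs, gp.gain)),
            "gain_10hz": float(np.interp(10.0, gp.freqs, gp.gain)),
            "gain_20hz": float(np.interp(20.0, gp.freqs, gp.gain)),
        }
    if "vclamp" in sets:
        steps_res = ih_step_amplitudes(sets["vclamp"])
        row = {
            "ih_max_pa": float(np.max(steps_res.ih_amplitude)),
            "tail_max_pa": float(np.nanmax(steps_res.tail_amplitude)),
        }
        try:
            act = activation_curve(steps_res)
            row["v50_mv"] = act.v50
            row["k_mv"] = act.k
        except ValueError:
            pass
        out["vclamp"] = row
    return out


def run_cohort_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every applicable analysis per cell and write the report bundle."""
    cohort_dir = Path(cfg.cohort_dir)
    if not cohort_dir.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {cohort_dir}")
    cells = _discover_cells(cohort_dir)
    if not cells:
        raise FileNotFoundError(f"no cell manifests under {cohort_dir}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list] = {k: [] for k in ("features", "impedance", "gain", "vclamp")}
    vectors = []
    errors = []
    for cell_id, manifests in cells.items():
        try:
            res = _analyze_cell(cell_id, manifests, cfg)
        except Exception as exc:  # per-cell isolation: report and continue
            errors.append({"cell_id": cell_id, "error": f"{type(exc).__name__}: {exc}"})
            continue
        for key in tables:
            if key in res:
                tables[key].append({"cell_id": cell_id, **res[key]})
        if "vector" in res:
            vectors.append(res["vector"])

    frames: dict[str, pd.DataFrame] = {}
    for key, rows in tables.items():
        if rows:
            frames[key] = pd.DataFrame(rows).set_index("cell_id").sort_index()
            frames[key].to_csv(out_dir / f"{key}.csv")
    if cfg.embed and len(vectors) >= cfg.min_cells_for_embedding:
        try:
            emb = embed_cohort(vectors, seed=cfg.seed,
                               min_cells=cfg.min_cells_for_embedding)
            frames["embedding"] = emb.coordinates
            emb.coordinates.to_csv(out_dir / "embedding.csv")
        except ValueError as exc:
            errors.append({"cell_id": "<embedding>", "error": str(exc)})
    err_frame = pd.DataFrame(errors, columns=["cell_id", "error"])
    err_frame.to_csv(out_dir / "errors.csv", index=False)
    frames["errors"] = err_frame

    provenance = {
        "package_version": __version__,
        "seed": int(cfg.seed),
        "cohort_dir": str(cohort_dir),
        "n_cells": len(cells),
        "zap": dataclasses.asdict(cfg.zap),
        "gain_max_lag_s": cfg.gain_max_lag,
        "embed": cfg.embed,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return frames
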