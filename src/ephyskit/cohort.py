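"""Per-cell feature vectors, multivariate embedding, and group statistics.

Fourteen named sub- and suprathreshold features define each cell:
RMP, input resistance, membrane time constant, sag ratio, sag amplitude
(subthreshold); AP threshold, amplitude, half-width, upstroke–downstroke
ratio, AHP amplitude, rheobase, latency (first AP at rheobase); f–I
slope and hero-sweep average rate (train). Missing entries are carried
explicitly in a completeness mask, never as silent zeros.

The embedding standardizes features (zero mean, unit variance over the
included cells), drops cells missing more than two features, imputes the
rest by feature medians, and runs UMAP with default parameters —
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .passive import PassiveFeatures
from .spikes import APWaveformFeatures, TrainFeatures

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "EmbeddingResult",
    "assemble_feature_vector",
    "cohort_table",
    "table_to_vectors",
    "embed_cohort",
    "group_stats",
]

FEATURE_NAMES = (
    "rmp",
    "input_resistance",
    "tau_m",
    "sag_ratio",
    "sag_amplitude",
    "ap_threshold",
    "ap_amplitude",
    "ap_half_width",
    "upstroke_downstroke_ratio",
    "ahp_amplitude",
    "rheobase",
    "latency",
    "fi_slope",
    "avg_rate_hero",
)

_SUPRATHRESHOLD = FEATURE_NAMES[5:]


@dataclass
class FeatureVector:
    """The 14 named features of one cell plus a completeness mask."""

    cell_id: str
    values: dict[str, float]
    mask: dict[str, bool] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing fields: {sorted(missing)}")
        if not self.mask:
            self.mask = {k: bool(np.isfinite(self.values[k])) for k in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.values[k] if self.mask[k] else np.nan for k in FEATURE_NAMES]
        )

    @property
    def n_present(self) -> int:
        return sum(self.mask.values())


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # index cell_id, columns umap_1, umap_2
    seed: int
    parameters: dict
    dropped_cells: list[str]
    annotations: pd.DataFrame


def assemble_feature_vector(
    passive: PassiveFeatures,
    ap: APWaveformFeatures | None,
    train: TrainFeatures | None,
    cell_id: str = "",
    annotations: dict | None = None,
) -> FeatureVector:
    """Map the module outputs one-to-one onto the 14-feature vector.

    With no suprathreshold sweeps (``ap``/``train`` absent) the nine
    suprathreshold fields are marked missing.
    """
    nan = float("nan")
    values = {
        "rmp": passive.rmp,
        "input_resistance": passive.input_resistance,
        "tau_m": passive.tau_m,
        "sag_ratio": passive.sag_ratio,
        "sag_amplitude": passive.sag_amplitude,
        "ap_threshold": ap.threshold if ap else nan,
        "ap_amplitude": ap.amplitude if ap else nan,
        "ap_half_width": ap.half_width if ap else nan,
        "upstroke_downstroke_ratio": ap.upstroke_downstroke_ratio if ap else nan,
        "ahp_amplitude": ap.ahp_amplitude if ap else nan,
        "rheobase": train.rheobase if train else nan,
        "latency": ap.latency if ap else nan,
        "fi_slope": train.fi_slope if train else nan,
        "avg_rate_hero": train.avg_rate_hero if train else nan,
    }
    return FeatureVector(cell_id, values, annotations=annotations or {})


def cohort_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Flat table: one row per cell, feature columns, mask columns, annotations."""
    rows = []
    for v in vectors:
        row: dict[str, object] = {"cell_id": v.cell_id}
        for k in FEATURE_NAMES:
            row[k] = v.values[k] if v.mask[k] else np.nan
            row[f"{k}_present"] = v.mask[k]
        row.update(v.annotations)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def table_to_vectors(table: pd.DataFrame) -> list[FeatureVector]:
    """Inverse of :func:`cohort_table` (round-trips the vector exactly)."""
    out = []
    ann_cols = [
        c for c in table.columns
        if c not in FEATURE_NAMES and not c.endswith("_present")
    ]
    for cell_id, row in table.iterrows():
        values = {k: float(row[k]) for k in FEATURE_NAMES}
        mask = {
            k: bool(row.get(f"{k}_present", np.isfinite(values[k])))
            for k in FEATURE_NAMES
        }
        out.append(FeatureVector(str(cell_id), values, mask,
                                 {c: row[c] for c in ann_cols}))
    return out


def embed_cohort(
    vectors: list[FeatureVector] | pd.DataFrame,
    seed: int = 0,
    min_cells: int = 10,
    max_missing: int = 2,
) -> EmbeddingResult:
    """Two-dimensional UMAP embedding of the standardized feature matrix.

    Cells missing more than ``max_missing`` of the 14 features are dropped
    (reported); remaining gaps are imputed by feature medians. Features
    are standardized to zero mean and unit variance before embedding.
    """
    import umap
    from sklearn.preprocessing import StandardScaler

    if isinstance(vectors, pd.DataFrame):
        vectors = table_to_vectors(vectors)
    kept, dropped = [], []
    for v in vectors:
        (kept if v.n_present >= len(FEATURE_NAMES) - max_missing else dropped).append(v)
    if len(kept) < min_cells:
        raise ValueError(
            f"embedding needs >= {min_cells} sufficiently complete cells, "
            f"got {len(kept)}"
        )
    x = np.stack([v.as_array() for v in kept])
    med = np.nanmedian(x, axis=0)
    fill = np.where(np.isnan(x), np.broadcast_to(med, x.shape), x)
    z = StandardScaler().fit_transform(fill)
    reducer = umap.UMAP(n_components=2, random_state=int(seed))
    coords = reducer.fit_transform(z)
    index = pd.Index([v.cell_id for v in kept], name="cell_id")
    frame = pd.DataFrame(coords, columns=["umap_1", "umap_2"], index=index)
    ann = pd.DataFrame([v.annotations for v in kept], index=index)
    return EmbeddingResult(
        coordinates=frame,
        seed=int(seed),
        parameters={"n_components": 2, "umap_defaults": True},
        dropped_cells=[v.cell_id for v in dropped],
        annotations=ann,
    )


def group_stats(
    values,
    labels=None,
    design: str = "independent",
) -> tuple[float, float]:
    """Two-group comparison: rank-sum (independent) or matched-pairs
    signed-rank (paired).

    ``values``/``labels`` give per-cell scalars with group labels, or for
    the paired design ``values`` may be a (before, after) pair of
    equal-length arrays. Identical paired samples return p = 1 (no
    nonzero differences).
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    if labels is None:
        a, b = (np.asarray(v, dtype=float) for v in values)
    else:
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        groups = pd.unique(labels)
        if len(groups) != 2:
            raise ValueError(f"exactly 2 groups required, got {len(groups)}")
        a = values[labels == groups[0]]
        b = values[labels == groups[1]]
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal-length matched samples")
        if np.allclose(a, b):
            return 0.0, 1.0
        res = wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
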