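"""Temporal and spectral metrics, feature tables, sidedness folding, and the
combined bi-modality table.

Feature names follow the grammar ``<relation>.<side|min|max>.<channel>.<metric>``
for sided relations and ``<relation>.<channel>.<metric>`` otherwise, where
channel is ``value`` or ``deriv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch

from .preprocessing import Segment
from .relations import RelationalSeries

__all__ = [
    "SpectralConfig",
    "MetricRegistry",
    "temporal_metrics",
    "spectral_metrics",
    "build_feature_table",
    "fold_sidedness",
    "combine_modalities",
    "attach_labels",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("segment_id", "subject_id", "med_state", "modality", "label")


@dataclass
class SpectralConfig:
    nperseg: int = 128
    overlap_frac: float = 0.5
    window: str = "hann"
    detrend: str = "constant"
    total_band: tuple[float, float] = (0.25, np.inf)  # upper clipped to Nyquist

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")


@dataclass
class MetricRegistry:
    """Default 13 metrics: 8 temporal + 3 relative band powers + dominant
    frequency + normalized spectral entropy, applied to value and derivative
    channels alike."""

    temporal: tuple[str, ...] = (
        "mean", "std", "median", "mad", "min", "max", "range", "rms",
    )
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "relpow_0.5_1": (0.5, 1.0),
        "relpow_2_4": (2.0, 4.0),
        "relpow_4_6": (4.0, 6.0),
    })
    spectral_extras: tuple[str, ...] = ("dominant_freq", "spectral_entropy")

    @property
    def names(self) -> list[str]:
        return list(self.temporal) + list(self.bands) + list(self.spectral_extras)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("metric names must be unique")


def temporal_metrics(x: np.ndarray) -> dict[str, float]:
    """Distribution summary: mean, population std, median, raw MAD, min, max,
    range, rms."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    med = float(np.median(x))
    return {
        "mean": float(np.mean(x)),
        "std": float(np.std(x)),  # ddof=0
        "median": med,
        "mad": float(np.median(np.abs(x - med))),  # unscaled
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "range": float(np.max(x) - np.min(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
    }


def _psd(x: np.ndarray, fps: float, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(len(x), cfg.nperseg)
    noverlap = int(nperseg * cfg.overlap_frac)
    return welch(
        x - np.mean(x), fs=fps, window=cfg.window,
        nperseg=nperseg, noverlap=noverlap, detrend=cfg.detrend,
    )


def spectral_metrics(
    x: np.ndarray,
    fps: float,
    cfg: SpectralConfig | None = None,
    registry: MetricRegistry | None = None,
) -> dict[str, float]:
    """Relative band powers, dominant frequency, and normalized spectral
    entropy of the Welch PSD over the total band.

    A constant series (zero total power) yields all-zero metrics by
    convention.
    """
    cfg = cfg or SpectralConfig()
    registry = registry or MetricRegistry()
    x = np.asarray(x, dtype=float)
    freqs, psd = _psd(x, fps, cfg)
    lo, hi = cfg.total_band
    hi = min(hi, fps / 2)
    in_band = (freqs >= lo) & (freqs <= hi)
    total = float(psd[in_band].sum())
    out: dict[str, float] = {}
    if total <= 0 or not in_band.any():
        for name in registry.bands:
            out[name] = 0.0
        out["dominant_freq"] = 0.0
        out["spectral_entropy"] = 0.0
        return out
    for name, (b_lo, b_hi) in registry.bands.items():
        sel = in_band & (freqs >= b_lo) & (freqs <= b_hi)
        out[name] = float(psd[sel].sum()) / total
    band_freqs = freqs[in_band]
    band_psd = psd[in_band]
    out["dominant_freq"] = float(band_freqs[np.argmax(band_psd)])
    p = band_psd / band_psd.sum()
    nz = p[p > 0]
    n_bins = len(p)
    out["spectral_entropy"] = (
        float(-(nz * np.log(nz)).sum() / np.log(n_bins)) if n_bins > 1 else 0.0
    )
    return out


def _feature_name(rel: RelationalSeries, channel: str, metric: str) -> str:
    if rel.side == "none":
        return f"{rel.name}.{channel}.{metric}"
    return f"{rel.name}.{rel.side}.{channel}.{metric}"


def segment_features(
    rels: list[RelationalSeries],
    fps: float,
    registry: MetricRegistry | None = None,
    spectral_cfg: SpectralConfig | None = None,
) -> dict[str, float]:
    """All (relation, channel, metric) values for one segment."""
    registry = registry or MetricRegistry()
    out: dict[str, float] = {}
    for rel in rels:
        channels = {"value": rel.values}
        if rel.derivative is not None:
            channels["deriv"] = rel.derivative
        for channel, series in channels.items():
            metrics = temporal_metrics(series)
            metrics.update(spectral_metrics(series, fps, spectral_cfg, registry))
            for metric in registry.names:
                out[_feature_name(rel, channel, metric)] = metrics[metric]
    return out


def build_feature_table(
    segment_relations: list[tuple[Segment, list[RelationalSeries]]],
    registry: MetricRegistry | None = None,
    spectral_cfg: SpectralConfig | None = None,
) -> pd.DataFrame:
    """One row per segment, metadata columns first, features in sorted order.

    Raises on any non-finite feature value, naming the segment and feature.
    """
    registry = registry or MetricRegistry()
    rows = []
    for seg, rels in segment_relations:
        feats = segment_features(rels, seg.series.fps, registry, spectral_cfg)
        for name, val in feats.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite feature {name!r} in segment {seg.segment_id}")
        row = {
            "segment_id": seg.segment_id,
            "subject_id": seg.series.subject_id,
            "med_state": seg.series.med_state,
            "modality": seg.series.modality,
        }
        row.update(feats)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["segment_id", "subject_id", "med_state", "modality"])
    df = pd.DataFrame(rows)
    meta = [c for c in METADATA_COLUMNS if c in df.columns]
    feats_sorted = sorted(c for c in df.columns if c not in meta)
    return df[meta + feats_sorted]


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def fold_sidedness(table: pd.DataFrame) -> pd.DataFrame:
    """Replace each (left, right) feature pair with per-row (min, max).

    Eliminates body sidedness so unilateral manifestations on opposite sides
    become comparable. Unpaired features pass through; column count is
    preserved. Idempotent.
    """
    cols = feature_columns(table)
    lefts = [c for c in cols if ".left." in c]
    folded: dict[str, pd.Series] = {}
    dropped: set[str] = set()
    for lcol in lefts:
        rcol = lcol.replace(".left.", ".right.")
        if rcol not in table.columns:
            raise ValueError(f"left feature {lcol!r} has no right counterpart")
        folded[lcol.replace(".left.", ".min.")] = np.minimum(table[lcol], table[rcol])
        folded[lcol.replace(".left.", ".max.")] = np.maximum(table[lcol], table[rcol])
        dropped.update((lcol, rcol))
    orphan_rights = [c for c in cols if ".right." in c and c not in dropped]
    if orphan_rights:
        raise ValueError(f"right features without left counterpart: {orphan_rights}")
    keep = [c for c in table.columns if c not in dropped]
    out = pd.concat([table[keep], pd.DataFrame(folded, index=table.index)], axis=1)
    meta = [c for c in METADATA_COLUMNS if c in out.columns]
    return out[meta + sorted(feature_columns(out))]


def attach_labels(table: pd.DataFrame, labels: dict[tuple[str, str], str]) -> pd.DataFrame:
    """Join severity labels on (subject_id, med_state); unlabeled rows drop."""
    out = table.copy()
    keys = list(zip(out["subject_id"].astype(str), out["med_state"].astype(str)))
    out["label"] = [labels.get(k) for k in keys]
    out = out[out["label"].notna()].reset_index(drop=True)
    meta = [c for c in METADATA_COLUMNS if c in out.columns]
    return out[meta + sorted(feature_columns(out))]


def combine_modalities(body: pd.DataFrame, hand: pd.DataFrame) -> pd.DataFrame:
    """Cartesian product of body x hand rows within each (subject, med_state).

    Features are concatenated with ``body.``/``hand.`` prefixes; both inputs
    must be labeled and folded, and labels must agree within a group.
    """
    for name, df in (("body", body), ("hand", hand)):
        if "label" not in df.columns:
            raise ValueError(f"{name} table is not labeled")
    b_feats = feature_columns(body)
    h_feats = feature_columns(hand)
    rows = []
    b_groups = body.groupby(["subject_id", "med_state"], sort=True)
    h_groups = dict(iter(hand.groupby(["subject_id", "med_state"], sort=True)))
    for key, b_grp in b_groups:
        h_grp = h_groups.get(key)
        if h_grp is None:
            continue
        labels = set(b_grp["label"]) | set(h_grp["label"])
        if len(labels) > 1:
            raise ValueError(f"label disagreement within group {key}: {labels}")
        for b_row in b_grp.to_dict(orient="records"):
            for h_row in h_grp.to_dict(orient="records"):
                row = {
                    "segment_id": f"{b_row['segment_id']}+{h_row['segment_id']}",
                    "subject_id": key[0],
                    "med_state": key[1],
                    "modality": "combined",
                    "label": b_row["label"],
                }
                row.update({f"body.{c}": b_row[c] for c in b_feats})
                row.update({f"hand.{c}": h_row[c] for c in h_feats})
                rows.append(row)
    if not rows:
        return pd.DataFrame(columns=list(METADATA_COLUMNS))
    df = pd.DataFrame(rows)
    meta = [c for c in METADATA_COLUMNS if c in df.columns]
    return df[meta + sorted(feature_columns(df))]
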