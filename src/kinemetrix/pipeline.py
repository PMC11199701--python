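"""End-to-end orchestration: data directory -> feature tables -> CV -> reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .features import (
    MetricRegistry,
    SpectralConfig,
    attach_labels,
    build_feature_table,
    combine_modalities,
    fold_sidedness,
)
from .io import LabelConfig, dichotomize, read_landmark_series, read_manifest
from .preprocessing import Segment, SegmentationConfig, SmoothingConfig, preprocess_recording
from .relations import RelationRegistry, default_registry, relations_for_segment

logger = logging.getLogger(__name__)

__all__ = ["ExtractionConfig", "ExtractionResult", "extract_features", "segment_index"]


@dataclass
class ExtractionConfig:
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    labels: LabelConfig = field(default_factory=LabelConfig)
    registry: RelationRegistry = field(default_factory=default_registry)
    metrics: MetricRegistry = field(default_factory=MetricRegistry)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    keep_going: bool = False


@dataclass
class ExtractionResult:
    body: pd.DataFrame
    hand: pd.DataFrame
    combined: pd.DataFrame
    segments: list[Segment]
    failures: dict[str, str]


def extract_features(data_dir: str | Path, cfg: ExtractionConfig | None = None) -> ExtractionResult:
    """Run the full extraction chain over every landmark CSV in a directory.

    Expects ``manifest.csv`` plus per-recording ``<id>.csv``/``<id>.json``
    pairs as written by the simulator (or any adapter producing the same
    layout).
    """
    cfg = cfg or ExtractionConfig()
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.csv")
    labels = dichotomize(manifest, cfg.labels)

    per_modality: dict[str, list] = {"body": [], "hand": []}
    all_segments: list[Segment] = []
    failures: dict[str, str] = {}
    paths = sorted(p for p in data_dir.glob("*.csv") if p.name != "manifest.csv")
    for path in paths:
        try:
            series = read_landmark_series(path)
            segments = preprocess_recording(series, cfg.smoothing, cfg.segmentation)
            if not segments:
                logger.warning("recording %s produced 0 segments", series.recording_id)
            for seg in segments:
                rels = relations_for_segment(seg, cfg.registry)
                per_modality[series.modality].append((seg, rels))
                all_segments.append(seg)
        except Exception as exc:  # noqa: BLE001 - per-recording isolation
            failures[path.name] = str(exc)
            logger.error("failed on %s: %s", path.name, exc)
            if not cfg.keep_going:
                raise

    tables = {}
    for modality in ("body", "hand"):
        table = build_feature_table(per_modality[modality], cfg.metrics, cfg.spectral)
        if len(table):
            table = fold_sidedness(table)
            table = attach_labels(table, labels)
        tables[modality] = table
    body, hand = tables["body"], tables["hand"]
    combined = (
        combine_modalities(body, hand)
        if len(body) and len(hand)
        else pd.DataFrame()
    )
    return ExtractionResult(
        body=body, hand=hand, combined=combined, segments=all_segments, failures=failures
    )


def segment_index(segments: list[Segment]) -> pd.DataFrame:
    """Flat index of emitted segments for auditing."""
    return pd.DataFrame([
        {
            "segment_id": s.segment_id,
            "recording_id": s.recording_id,
            "subject_id": s.series.subject_id,
            "med_state": s.series.med_state,
            "modality": s.series.modality,
            "start_frame": s.start_frame,
            "end_frame": s.end_frame,
            "duration_s": s.duration_s,
        }
        for s in segments
    ])
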