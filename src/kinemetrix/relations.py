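"""Relational kinematic time series: angles, distances, displacements.

Each registry entry turns a segment's landmark trajectories into one scalar
series per frame, later scale-normalized per frame (body length or active-hand
palm length) and differentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .preprocessing import Segment

__all__ = [
    "RelationalSeries",
    "Relation",
    "RelationRegistry",
    "default_registry",
    "angle_between",
    "compute_relations",
    "normalize_relations",
    "differentiate",
    "relations_for_segment",
]

Kind = str  # "angle" | "distance" | "h_disp" | "v_disp"


@dataclass
class RelationalSeries:
    """One named scalar time series for a segment, with optional derivative."""

    name: str
    side: str  # "left" | "right" | "none"
    kind: Kind
    values: np.ndarray
    segment_id: str
    derivative: np.ndarray | None = None

    @property
    def key(self) -> str:
        return self.name if self.side == "none" else f"{self.name}.{self.side}"


@dataclass(frozen=True)
class Relation:
    name: str
    side: str
    kind: Kind
    fn: Callable[[Segment], np.ndarray]
    modality: str


def _mid(seg: Segment, a: str, b: str) -> np.ndarray:
    return 0.5 * (seg.series.xy(a) + seg.series.xy(b))


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at vertex ``b`` between rays to ``a`` and ``c``, in degrees [0, 180].

    Vectorized over leading axes; inputs are (..., 2) points.
    """
    u = np.asarray(a, dtype=float) - b
    v = np.asarray(c, dtype=float) - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    if np.any(denom == 0):
        raise ValueError("zero-length limb vector")
    cos = np.clip((u * v).sum(axis=-1) / denom, -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def _dist(seg: Segment, a: str, b: str) -> np.ndarray:
    return np.linalg.norm(seg.series.xy(a) - seg.series.xy(b), axis=1)


def _active_xy(seg: Segment, landmark: str) -> np.ndarray:
    """Per-frame coordinates of ``landmark`` on the active hand."""
    if seg.active_hand is None:
        raise ValueError("hand segment lacks active-hand record")
    hands = seg.series.hands
    if len(hands) == 1:
        return seg.series.xy(f"{hands[0]}_{landmark}")
    left = seg.series.xy(f"left_{landmark}")
    right = seg.series.xy(f"right_{landmark}")
    is_left = np.asarray(seg.active_hand) == "left"
    return np.where(is_left[:, None], left, right)


def _body_relations() -> list[Relation]:
    rels: list[Relation] = [
        Relation(
            "neck_angle", "none", "angle",
            lambda s: angle_between(
                s.series.xy("nose"),
                _mid(s, "left_shoulder", "right_shoulder"),
                s.series.xy("left_shoulder"),
            ),
            "body",
        ),
    ]
    for side in ("left", "right"):
        rels.append(Relation(
            "arm_body_lateral_angle", side, "angle",
            lambda s, sd=side: angle_between(
                s.series.xy(f"{sd}_elbow"),
                s.series.xy(f"{sd}_shoulder"),
                s.series.xy(f"{sd}_hip"),
            ),
            "body",
        ))
    for side in ("left", "right"):
        rels.append(Relation(
            "wrist_shoulder_distance", side, "distance",
            lambda s, sd=side: _dist(s, f"{sd}_wrist", f"{sd}_shoulder"), "body",
        ))
        rels.append(Relation(
            "ankle_hip_distance", side, "distance",
            lambda s, sd=side: _dist(s, f"{sd}_ankle", f"{sd}_hip"), "body",
        ))
    # signed differences: left - right (lateral) and upper - lower (sway)
    rels += [
        Relation("ankle_separation", "none", "h_disp",
                 lambda s: s.series.x("left_ankle") - s.series.x("right_ankle"), "body"),
        Relation("knee_separation", "none", "h_disp",
                 lambda s: s.series.x("left_knee") - s.series.x("right_knee"), "body"),
        Relation("body_sway", "none", "h_disp",
                 lambda s: _mid(s, "left_shoulder", "right_shoulder")[:, 0]
                 - _mid(s, "left_hip", "right_hip")[:, 0], "body"),
        Relation("leg_raise", "none", "v_disp",
                 lambda s: s.series.y("left_ankle") - s.series.y("right_ankle"), "body"),
        Relation("shoulder_tilt", "none", "v_disp",
                 lambda s: s.series.y("left_shoulder") - s.series.y("right_shoulder"), "body"),
        Relation("hip_tilt", "none", "v_disp",
                 lambda s: s.series.y("left_hip") - s.series.y("right_hip"), "body"),
    ]
    return rels


def _hand_relations() -> list[Relation]:
    def tip_to_wrist(tip: str) -> Callable[[Segment], np.ndarray]:
        return lambda s: np.linalg.norm(_active_xy(s, tip) - _active_xy(s, "wrist"), axis=1)

    return [
        Relation("finger_tapping", "none", "distance",
                 lambda s: np.linalg.norm(
                     _active_xy(s, "thumb_tip") - _active_xy(s, "index_tip"), axis=1), "hand"),
        Relation("middle_finger_movement", "none", "distance", tip_to_wrist("middle_tip"), "hand"),
        Relation("ring_finger_movement", "none", "distance", tip_to_wrist("ring_tip"), "hand"),
        Relation("pinky_finger_movement", "none", "distance", tip_to_wrist("pinky_tip"), "hand"),
    ]


@dataclass
class RelationRegistry:
    relations: list[Relation] = field(default_factory=lambda: _body_relations() + _hand_relations())

    def __post_init__(self) -> None:
        keys = [(r.name, r.side) for r in self.relations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate relation (name, side)")

    def for_modality(self, modality: str) -> list[Relation]:
        return [r for r in self.relations if r.modality == modality]


def default_registry() -> RelationRegistry:
    return RelationRegistry()


def compute_relations(seg: Segment, registry: RelationRegistry | None = None) -> list[RelationalSeries]:
    """Evaluate every registry relation of the segment's modality."""
    registry = registry or default_registry()
    rels = registry.for_modality(seg.series.modality)
    if not rels:
        raise ValueError(f"registry has no relations for modality {seg.series.modality!r}")
    return [
        RelationalSeries(
            name=r.name, side=r.side, kind=r.kind,
            values=np.asarray(r.fn(seg), dtype=float),
            segment_id=seg.segment_id,
        )
        for r in rels
    ]


def scale_reference(seg: Segment) -> np.ndarray:
    """Per-frame scale: body length (mid-shoulder to mid-hip) or active-hand
    palm length (wrist to midpoint of index/pinky MCPs)."""
    if seg.series.modality == "body":
        ref = np.linalg.norm(
            _mid(seg, "left_shoulder", "right_shoulder") - _mid(seg, "left_hip", "right_hip"),
            axis=1,
        )
    else:
        mid_mcp = 0.5 * (_active_xy(seg, "index_mcp") + _active_xy(seg, "pinky_mcp"))
        ref = np.linalg.norm(_active_xy(seg, "wrist") - mid_mcp, axis=1)
    if np.any(ref <= 1e-9):
        raise ValueError("zero or near-zero scale reference; upstream filtering failed")
    return ref


def normalize_relations(rels: list[RelationalSeries], seg: Segment) -> list[RelationalSeries]:
    """Divide distance/displacement series frame-wise by the scale reference.

    Angle series are dimensionless and pass through unchanged.
    """
    ref = scale_reference(seg)
    out = []
    for r in rels:
        if r.kind == "angle":
            out.append(r)
        else:
            out.append(replace(r, values=r.values / ref))
    return out


def differentiate(rel: RelationalSeries, fps: float) -> RelationalSeries:
    """Forward difference scaled to per-second units; length n-1."""
    if len(rel.values) < 2:
        raise ValueError("need at least 2 frames to differentiate")
    return replace(rel, derivative=np.diff(rel.values) * fps)


def relations_for_segment(
    seg: Segment, registry: RelationRegistry | None = None
) -> list[RelationalSeries]:
    """compute -> normalize -> differentiate, in one call."""
    rels = normalize_relations(compute_relations(seg, registry), seg)
    return [differentiate(r, seg.series.fps) for r in rels]
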