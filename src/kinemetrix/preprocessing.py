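"""Smoothing, validity rules, invalid-window dilation, and segmentation.

Processing order: smooth -> rule masks -> union with input invalidity ->
dilate -> cut into 3-8 s artifact-free segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .io import LandmarkSeries

__all__ = [
    "SmoothingConfig",
    "SegmentationConfig",
    "Segment",
    "gaussian_kernel",
    "gaussian_smooth",
    "body_validity_mask",
    "flicker_mask",
    "hand_validity_mask",
    "dilate_invalid",
    "segment",
    "preprocess_recording",
]


@dataclass
class SmoothingConfig:
    window: int = 5
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SegmentationConfig:
    min_duration_s: float = 3.0
    max_duration_s: float = 8.0
    invalid_halo_s: float = 0.333
    flicker_window_s: float = 0.5
    flicker_min_crossings: int = 3
    smooth_before_masks: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_duration_s <= self.max_duration_s:
            raise ValueError("need 0 < min_duration_s <= max_duration_s")
        if self.invalid_halo_s < 0:
            raise ValueError("invalid_halo_s must be >= 0")


@dataclass
class Segment:
    """A contiguous artifact-free window of a recording, 3-8 s long."""

    segment_id: str
    recording_id: str
    start_frame: int
    end_frame: int  # half-open
    series: LandmarkSeries
    active_hand: np.ndarray | None = field(default=None)  # per-frame "left"/"right"

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.series.fps


def gaussian_kernel(window: int = 5, sigma: float = 0.5) -> np.ndarray:
    """Normalized discrete Gaussian over a centered window."""
    half = window // 2
    k = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def gaussian_smooth(series: LandmarkSeries, cfg: SmoothingConfig | None = None) -> LandmarkSeries:
    """Convolve every coordinate channel with a rolling Gaussian window.

    Edges use the truncated kernel renormalized to unit mass, so constants are
    preserved everywhere. Validity flags pass through unchanged.
    """
    cfg = cfg or SmoothingConfig()
    if series.frames < 2:
        return series
    kernel = gaussian_kernel(cfg.window, cfg.sigma)
    n, m, _ = series.coords.shape
    flat = series.coords.reshape(n, m * 2)
    norm = np.convolve(np.ones(n), kernel, mode="same")
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        out[:, j] = np.convolve(flat[:, j], kernel, mode="same") / norm
    from dataclasses import replace

    return replace(series, coords=out.reshape(n, m, 2), validity=series.validity.copy())


def _leg_ok(series: LandmarkSeries, side: str) -> np.ndarray:
    lower = np.linalg.norm(series.xy(f"{side}_ankle") - series.xy(f"{side}_knee"), axis=1)
    upper = np.linalg.norm(series.xy(f"{side}_hip") - series.xy(f"{side}_knee"), axis=1)
    # "at most twice": ties count as standing
    return lower <= 2.0 * upper


def body_validity_mask(series: LandmarkSeries) -> np.ndarray:
    """Standing + facing rules for body recordings.

    A frame is valid iff both apparent lower legs are at most twice the upper
    legs, the wrist-hip horizontal offsets have opposite signs (subject faces
    the camera or away from it), and the frame was not already flagged.
    """
    if series.modality != "body":
        raise ValueError("body_validity_mask requires body modality")
    standing = _leg_ok(series, "left") & _leg_ok(series, "right")
    dl = series.x("left_wrist") - series.x("left_hip")
    dr = series.x("right_wrist") - series.x("right_hip")
    facing = np.sign(dl) * np.sign(dr) < 0
    return standing & facing & series.validity


def flicker_mask(series: LandmarkSeries, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """True where rapid zero-crossings of the inter-shoulder x-difference occur.

    A frame is flagged if any window of ``flicker_window_s`` covering it
    contains at least ``flicker_min_crossings`` sign changes.
    """
    if series.modality != "body":
        raise ValueError("flicker_mask requires body modality")
    cfg = cfg or SegmentationConfig()
    d = series.x("left_shoulder") - series.x("right_shoulder")
    n = len(d)
    w = max(int(round(cfg.flicker_window_s * series.fps)), 2)
    s = np.sign(d)
    # crossing[i] == 1 when sign changes between frames i and i+1
    crossing = (s[:-1] * s[1:] < 0).astype(int)
    if n <= 1 or crossing.sum() < cfg.flicker_min_crossings:
        return np.zeros(n, dtype=bool)
    flagged = np.zeros(n, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(crossing)])
    for a in range(0, n - w + 1):
        # window covers frames [a, a+w); crossings inside: indices a..a+w-2
        if csum[a + w - 1] - csum[a] >= cfg.flicker_min_crossings:
            flagged[a : a + w] = True
    return flagged


def hand_validity_mask(series: LandmarkSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-and-only-one-raised-hand rule.

    Returns ``(valid, active)`` where ``active`` names the raised hand per
    frame ("left"/"right", "" when invalid). With two hands present a frame is
    valid iff the index-to-wrist vertical offsets have opposite signs; with
    one hand, iff that hand is raised (index above wrist under y-down).
    """
    if series.modality != "hand":
        raise ValueError("hand_validity_mask requires hand modality")
    hands = series.hands
    if not hands:
        raise ValueError("no hands present")
    n = series.frames
    active = np.full(n, "", dtype=object)
    if len(hands) == 2:
        dl = series.y("left_index_tip") - series.y("left_wrist")
        dr = series.y("right_index_tip") - series.y("right_wrist")
        valid = np.sign(dl) * np.sign(dr) < 0
        active[valid & (dl < 0)] = "left"
        active[valid & (dr < 0)] = "right"
    else:
        hand = hands[0]
        d = series.y(f"{hand}_index_tip") - series.y(f"{hand}_wrist")
        valid = d < 0  # raised: index above wrist, y-down
        active[valid] = hand
    valid = valid & series.validity
    active[~valid] = ""
    return valid, active


def halo_radius(invalid_halo_s: float, fps: float) -> int:
    """Halo radius in frames, round-half-up (0.333 s at 30 fps -> 10)."""
    return int(math.floor(invalid_halo_s * fps + 0.5))


def dilate_invalid(
    mask: np.ndarray, fps: float, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Mark every frame within the halo radius of an invalid frame invalid.

    ``mask`` is a validity mask (True = valid). Idempotent and monotone.
    """
    cfg = cfg or SegmentationConfig()
    r = halo_radius(cfg.invalid_halo_s, fps)
    invalid = ~np.asarray(mask, dtype=bool)
    if r == 0 or not invalid.any():
        return ~invalid
    dilated = binary_dilation(invalid, structure=np.ones(2 * r + 1, dtype=bool))
    return ~dilated


def _split_run(start: int, end: int, fps: float, cfg: SegmentationConfig) -> list[tuple[int, int]]:
    n = end - start
    duration = n / fps
    if duration < cfg.min_duration_s:
        return []
    if duration <= cfg.max_duration_s:
        return [(start, end)]
    k = math.ceil(duration / cfg.max_duration_s)
    base, rem = divmod(n, k)
    pieces = []
    pos = start
    for i in range(k):
        size = base + (1 if i < rem else 0)  # remainder to earliest pieces
        if size / fps >= cfg.min_duration_s:
            pieces.append((pos, pos + size))
        pos += size
    return pieces


def segment(
    series: LandmarkSeries,
    valid: np.ndarray,
    cfg: SegmentationConfig | None = None,
    active_hand: np.ndarray | None = None,
) -> list[Segment]:
    """Cut maximal valid runs into duration-bounded segments.

    Runs shorter than the minimum are discarded; runs longer than the maximum
    are split into ``ceil(T/max)`` equal pieces, each re-checked against the
    minimum. Segment ids are deterministic, ordered by start frame.
    """
    cfg = cfg or SegmentationConfig()
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != (series.frames,):
        raise ValueError("valid mask length mismatch")
    bounds: list[tuple[int, int]] = []
    padded = np.concatenate([[False], valid, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        bounds.extend(_split_run(int(s), int(e), series.fps, cfg))
    segments = []
    for i, (s, e) in enumerate(sorted(bounds)):
        seg = Segment(
            segment_id=f"{series.recording_id}_s{i:03d}",
            recording_id=series.recording_id,
            start_frame=s,
            end_frame=e,
            series=series.slice(s, e),
            active_hand=None if active_hand is None else np.asarray(active_hand[s:e]),
        )
        segments.append(seg)
    return segments


def preprocess_recording(
    series: LandmarkSeries,
    smoothing: SmoothingConfig | None = None,
    cfg: SegmentationConfig | None = None,
) -> list[Segment]:
    """Full preprocessing chain for one recording."""
    smoothing = smoothing or SmoothingConfig()
    cfg = cfg or SegmentationConfig()
    smoothed = gaussian_smooth(series, smoothing) if cfg.smooth_before_masks else series
    active = None
    if series.modality == "body":
        valid = body_validity_mask(smoothed)
        valid &= ~flicker_mask(smoothed, cfg)
    else:
        valid, active = hand_validity_mask(smoothed)
    valid = dilate_invalid(valid, series.fps, cfg)
    if not cfg.smooth_before_masks:
        smoothed = gaussian_smooth(series, smoothing)
    return segment(smoothed, valid, cfg, active_hand=active)
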