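"""Data model and readers/writers for landmark series, manifests, and labels.

Landmark series live in wide CSV files (one row per frame, ``frame`` column
plus ``<landmark>_x`` / ``<landmark>_y`` columns) with a JSON sidecar holding
recording metadata. Coordinates are image-normalized with y increasing
downward, the convention of the upstream pose estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "BODY_LANDMARKS",
    "HAND_LANDMARKS",
    "LandmarkSeries",
    "CohortManifest",
    "LabelConfig",
    "read_landmark_series",
    "write_landmark_series",
    "read_manifest",
    "dichotomize",
]

#: Ordered body landmark names (13).
BODY_LANDMARKS: tuple[str, ...] = (
    "nose",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)

#: Per-hand landmark names (8); in files they are prefixed ``left_``/``right_``.
HAND_LANDMARKS: tuple[str, ...] = (
    "wrist",
    "thumb_tip",
    "index_tip",
    "middle_tip",
    "ring_tip",
    "pinky_tip",
    "index_mcp",
    "pinky_mcp",
)

Modality = Literal["body", "hand"]
MedState = Literal["on", "off"]

MANIFEST_COLUMNS = (
    "subject_id", "med_state", "updrs3", "updrs1", "updrs2",
    "hoehn_yahr", "moca", "age", "sex", "handedness", "diagnosis",
)


def _expected_landmarks(modality: str, hands: tuple[str, ...] = ("left", "right")) -> list[str]:
    if modality == "body":
        return list(BODY_LANDMARKS)
    return [f"{h}_{name}" for h in hands for name in HAND_LANDMARKS]


@dataclass
class LandmarkSeries:
    """Per-frame 2D coordinates for a named landmark set.

    ``coords`` has shape ``(frames, n_landmarks, 2)`` with the last axis being
    (x, y). ``validity`` flags frames that are usable; invalid frames keep
    placeholder coordinates (held from the nearest valid frame) purely so that
    downstream convolutions stay finite — they are never imputed as data.
    """

    recording_id: str
    subject_id: str
    modality: Modality
    med_state: MedState
    fps: float
    landmark_names: list[str]
    coords: np.ndarray
    validity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (frames, n_landmarks, 2)")
        if self.coords.shape[1] != len(self.landmark_names):
            raise ValueError("coords second axis must match landmark_names")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.modality not in ("body", "hand"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.med_state not in ("on", "off"):
            raise ValueError(f"unknown med_state {self.med_state!r}")
        if self.validity is None:
            self.validity = np.ones(self.frames, dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != (self.frames,):
                raise ValueError("validity length must equal frames")
        self._check_landmark_set()

    def _check_landmark_set(self) -> None:
        names = set(self.landmark_names)
        if len(names) != len(self.landmark_names):
            raise ValueError("duplicate landmark names")
        if self.modality == "body":
            expected = set(BODY_LANDMARKS)
            if names != expected:
                raise ValueError(
                    "landmark set incomplete for body modality: "
                    f"missing {sorted(expected - names)}, extra {sorted(names - expected)}"
                )
        else:
            hands = self.hands
            if not hands:
                raise ValueError("landmark set incomplete for hand modality: no hands present")
            expected = set(_expected_landmarks("hand", hands))
            if names != expected:
                raise ValueError(
                    "landmark set incomplete for hand modality: "
                    f"missing {sorted(expected - names)}, extra {sorted(names - expected)}"
                )

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames / self.fps

    @property
    def hands(self) -> tuple[str, ...]:
        """Which hand prefixes are present (hand modality only)."""
        present = []
        for hand in ("left", "right"):
            if f"{hand}_wrist" in self.landmark_names:
                present.append(hand)
        return tuple(present)

    def index(self, name: str) -> int:
        return self.landmark_names.index(name)

    def xy(self, name: str) -> np.ndarray:
        """(frames, 2) view of one landmark's coordinates."""
        return self.coords[:, self.index(name), :]

    def x(self, name: str) -> np.ndarray:
        return self.coords[:, self.index(name), 0]

    def y(self, name: str) -> np.ndarray:
        return self.coords[:, self.index(name), 1]

    def slice(self, start: int, end: int) -> "LandmarkSeries":
        """Frame-slice [start, end) preserving metadata."""
        return replace(
            self,
            coords=self.coords[start:end].copy(),
            validity=self.validity[start:end].copy(),
        )


def read_landmark_series(path: str | Path) -> LandmarkSeries:
    """Read a wide landmark CSV and its JSON sidecar.

    Missing numeric cells mark the whole frame invalid rather than raising;
    the placeholder coordinates for such frames are filled from the nearest
    valid frame so smoothing never sees NaN.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("recording_id", "subject_id", "modality", "med_state"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing key {key!r}")
    modality = meta["modality"]
    if modality not in ("body", "hand"):
        raise ValueError(f"unknown modality {modality!r} in {sidecar}")
    fps = float(meta.get("fps", 30.0))

    df = pd.read_csv(path, float_precision="round_trip")
    if "frame" not in df.columns:
        raise ValueError(f"{path}: missing 'frame' column")
    frame_idx = df["frame"].to_numpy()
    if len(frame_idx) == 0:
        raise ValueError(f"{path}: no rows")
    if np.any(np.diff(frame_idx) <= 0):
        raise ValueError(f"{path}: non-monotone frame index")

    coord_cols = [c for c in df.columns if c.endswith(("_x", "_y"))]
    names = sorted({c[:-2] for c in coord_cols})
    if modality == "body":
        ordered = [n for n in BODY_LANDMARKS]
    else:
        hands = tuple(h for h in ("left", "right") if f"{h}_wrist" in names)
        ordered = _expected_landmarks("hand", hands)
    missing = [n for n in ordered if f"{n}_x" not in df.columns or f"{n}_y" not in df.columns]
    if missing or not ordered:
        raise ValueError(f"{path}: landmark set incomplete for {modality} modality: {missing}")

    n = len(df)
    coords = np.empty((n, len(ordered), 2), dtype=float)
    for j, name in enumerate(ordered):
        coords[:, j, 0] = df[f"{name}_x"].to_numpy(dtype=float)
        coords[:, j, 1] = df[f"{name}_y"].to_numpy(dtype=float)

    validity = ~np.isnan(coords).any(axis=(1, 2))
    if "valid" in df.columns:
        validity &= df["valid"].to_numpy(dtype=bool)
    if not validity.all():
        coords = _fill_invalid(coords, validity)

    return LandmarkSeries(
        recording_id=str(meta["recording_id"]),
        subject_id=str(meta["subject_id"]),
        modality=modality,
        med_state=meta["med_state"],
        fps=fps,
        landmark_names=ordered,
        coords=coords,
        validity=validity,
    )


def _fill_invalid(coords: np.ndarray, validity: np.ndarray) -> np.ndarray:
    """Hold coordinates of invalid frames from the nearest valid frame."""
    if not validity.any():
        return np.nan_to_num(coords, nan=0.0)
    valid_idx = np.flatnonzero(validity)
    pos = np.searchsorted(valid_idx, np.arange(len(validity)))
    left = valid_idx[np.clip(pos - 1, 0, len(valid_idx) - 1)]
    right = valid_idx[np.clip(pos, 0, len(valid_idx) - 1)]
    here = np.arange(len(validity))
    nearest = np.where(np.abs(here - left) <= np.abs(right - here), left, right)
    out = coords.copy()
    out[~validity] = coords[nearest[~validity]]
    return out


def write_landmark_series(series: LandmarkSeries, path: str | Path) -> Path:
    """Write CSV + JSON sidecar; inverse of :func:`read_landmark_series`.

    Coordinates round-trip bit-exactly (written with ``repr``-level precision).
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {"frame": np.arange(series.frames)}
    for j, name in enumerate(series.landmark_names):
        cols[f"{name}_x"] = series.coords[:, j, 0]
        cols[f"{name}_y"] = series.coords[:, j, 1]
    cols["valid"] = series.validity.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "recording_id": series.recording_id,
        "subject_id": series.subject_id,
        "modality": series.modality,
        "med_state": series.med_state,
        "fps": series.fps,
    }, indent=2))
    return path


@dataclass
class CohortManifest:
    """Clinical manifest keyed by (subject_id, med_state)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        if len(df) == 0:
            raise ValueError("manifest has no rows")
        for col in ("subject_id", "med_state", "updrs3"):
            if col not in df.columns:
                raise ValueError(f"manifest missing column {col!r}")
        keys = list(zip(df["subject_id"], df["med_state"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, med_state) rows")
        bad_state = set(df["med_state"]) - {"on", "off"}
        if bad_state:
            raise ValueError(f"unknown med_state values {sorted(bad_state)}")
        scores = df["updrs3"].dropna()
        if ((scores < 0) | (scores > 132)).any():
            raise ValueError("updrs3 out of range [0, 132]")

    @property
    def labeled(self) -> pd.DataFrame:
        """Rows with a usable updrs3 score (unlabeled rows are excluded)."""
        return self.rows[self.rows["updrs3"].notna()]

    def subjects(self) -> list[str]:
        return sorted(set(self.rows["subject_id"].astype(str)))


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no rows")
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortManifest(rows=df)


@dataclass
class LabelConfig:
    """Severity dichotomization rule: score strictly above threshold → high."""

    threshold_mode: Literal["sample_median", "fixed"] = "sample_median"
    fixed_threshold: float = 32.0

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_threshold <= 132:
            raise ValueError("fixed_threshold must be in [0, 132]")


def dichotomize(
    manifest: CohortManifest, cfg: LabelConfig | None = None
) -> dict[tuple[str, str], str]:
    """Label every scored (subject, med_state) row as ``low`` or ``high``.

    The same subject may carry different labels in different medication
    states. With ``sample_median`` the threshold is the median over all
    scored rows; the boundary case (score == threshold) is labeled low.
    """
    cfg = cfg or LabelConfig()
    rows = manifest.labeled
    if len(rows) == 0:
        raise ValueError("no scored rows to label")
    if cfg.threshold_mode == "sample_median":
        threshold = float(rows["updrs3"].median())
    else:
        threshold = cfg.fixed_threshold
    return {
        (str(r.subject_id), str(r.med_state)): ("high" if r.updrs3 > threshold else "low")
        for r in rows.itertuples()
    }
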