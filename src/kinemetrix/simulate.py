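"""Synthetic cohorts of gait and finger-tapping landmark recordings.

Severity effects are injected at the landmark level so that every pipeline
stage — filters, relations, normalization, metrics — is exercised. A severity
parameter theta in [0, 1] interpolates each effect gain log-linearly between
the mild (theta=0, multiplier 1) and severe (theta=1, full gain) endpoints.

The walker is schematic: fixed per-subject segment lengths with ~10 %
inter-subject variation, planar projection, y increasing downward. No
biomechanical fidelity is claimed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BODY_LANDMARKS, HAND_LANDMARKS, LandmarkSeries, write_landmark_series

__all__ = [
    "SeverityEffects",
    "ArtifactSpec",
    "SyntheticCohortConfig",
    "simulate_gait",
    "simulate_tapping",
    "inject_artifacts",
    "generate_cohort",
]


@dataclass
class SeverityEffects:
    """Severe-endpoint multipliers for each planted effect (all > 0).

    Gains > 1 amplify with severity, < 1 attenuate. Applied as ``gain**theta``.
    """

    ankle_sep_var_gain: float = 3.0       # inter-ankle oscillation amplitude, severe up
    hip_ankle_var_gain: float = 0.15      # vertical leg-length modulation, severe down
    neck_2_4hz_gain: float = 0.33         # 3 Hz neck-angle oscillation, severe down
    armswing_highfreq_gain: float = 0.30  # 5 Hz arm-swing component, severe down
    armswing_drift_gain: float = 3.0      # 0.7 Hz arm-swing drift, severe up
    tap_amplitude_gain: float = 0.40      # thumb-index excursion, severe down
    tap_speed_gain: float = 0.85          # tap frequency multiplier, severe down
    pinkie_comovement_gain: float = 3.0   # pinky-wrist oscillation, severe up
    tap_jerk_4_6hz_gain: float = 3.0      # 5 Hz jerk on tapping distance, severe up

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0")

    def at(self, theta: float) -> dict[str, float]:
        if not 0 <= theta <= 1:
            raise ValueError("theta must be in [0, 1]")
        return {name: value**theta for name, value in asdict(self).items()}

    @staticmethod
    def planted_patterns() -> dict[str, list[str]]:
        """Feature-name substrings affected by each planted effect, on the
        folded combined table. Used for recall/precision bookkeeping."""
        return {
            "ankle_sep_var": ["body.ankle_separation."],
            "hip_ankle_var": ["body.ankle_hip_distance."],
            "neck_2_4hz": ["body.neck_angle."],
            "armswing": ["body.arm_body_lateral_angle."],
            "tapping": ["hand.finger_tapping."],
            "pinkie": ["hand.pinky_finger_movement."],
        }


@dataclass
class ArtifactSpec:
    """Tracking artifacts injected to trigger each validity filter."""

    n_dropout: int = 0
    dropout_s: float = 0.3
    n_flicker: int = 0            # body: left/right shoulder x swapped per frame
    flicker_s: float = 0.2
    n_crouch: int = 0             # body: lower leg inflated beyond 2x upper leg
    crouch_s: float = 0.5
    n_both_raised: int = 0        # hand: resting index raised above wrist
    both_raised_s: float = 0.5
    min_gap_s: float = 4.0        # clean spacing between events

    def events(self, modality: str) -> list[tuple[str, float]]:
        kinds = [("dropout", self.dropout_s)] * self.n_dropout
        if modality == "body":
            kinds += [("flicker", self.flicker_s)] * self.n_flicker
            kinds += [("crouch", self.crouch_s)] * self.n_crouch
        else:
            kinds += [("both_raised", self.both_raised_s)] * self.n_both_raised
        return kinds


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 20
    recordings_per_subject: int = 1   # per modality
    duration_s: float = 40.0
    fps: float = 30.0
    fraction_severe: float = 0.5
    theta_mild: float = 0.2
    theta_severe: float = 0.8
    noise_sd: float = 0.002
    stride_freq_hz: float = 0.9
    tap_freq_hz: float = 2.5
    seed: int = 0
    effects: SeverityEffects = field(default_factory=SeverityEffects)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.duration_s < 10:
            raise ValueError("duration_s must be >= 10")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


_JITTER_KEYS = (
    "neck", "ankle_sep", "leg_stretch", "arm_hf", "arm_drift",
    "tap_amp", "tap_jerk", "pinky",
)


@dataclass
class SubjectParams:
    scale: float
    stride_freq: float
    tap_freq: float
    active_hand: str
    phase: float
    # per-subject lognormal multipliers on each effect amplitude, so
    # between-subject variance dominates within-recording noise
    amp_jitter: dict[str, float] = field(default_factory=lambda: dict.fromkeys(_JITTER_KEYS, 1.0))


def _subject_params(cfg: SyntheticCohortConfig, subject_idx: int) -> SubjectParams:
    rng = np.random.default_rng([cfg.seed, 1000 + subject_idx])
    jitter = {k: float(np.exp(rng.normal(0.0, 0.25))) for k in _JITTER_KEYS}
    return SubjectParams(
        scale=float(rng.uniform(0.9, 1.1)),
        stride_freq=float(cfg.stride_freq_hz * rng.uniform(0.95, 1.05)),
        tap_freq=float(cfg.tap_freq_hz * rng.uniform(0.95, 1.05)),
        active_hand=str(rng.choice(["left", "right"])),
        phase=float(rng.uniform(0, 2 * np.pi)),
        amp_jitter=jitter,
    )


def simulate_gait(
    params: SubjectParams,
    theta: float,
    duration_s: float,
    fps: float,
    seed: int,
    effects: SeverityEffects | None = None,
    noise_sd: float = 0.002,
    recording_id: str = "gait",
    subject_id: str = "s0",
    med_state: str = "off",
) -> LandmarkSeries:
    """A 13-landmark planar walker with theta-dependent planted effects."""
    effects = effects or SeverityEffects()
    g = effects.at(theta)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    s = params.scale
    w_stride = 2 * np.pi * params.stride_freq

    cx = 0.5 + 0.02 * np.sin(2 * np.pi * 0.05 * t + params.phase)
    hip_y = 0.55
    sh_y = hip_y - 0.20 * s  # body length stable per frame
    sw, hw = 0.08 * s, 0.06 * s

    # trunk, with theta-independent sway and tilts
    sway = 0.006 * np.sin(2 * np.pi * 0.3 * t + params.phase)
    msx = cx + sway
    tilt = 0.004 * np.sin(2 * np.pi * 0.5 * t)
    pos: dict[str, np.ndarray] = {}
    pos["left_shoulder"] = np.stack([msx - sw, sh_y + tilt + 0 * t], axis=1)
    pos["right_shoulder"] = np.stack([msx + sw, sh_y - tilt], axis=1)
    pos["left_hip"] = np.stack([cx - hw, hip_y + 0.6 * tilt], axis=1)
    pos["right_hip"] = np.stack([cx + hw, hip_y - 0.6 * tilt], axis=1)

    # neck: nose oscillates laterally at 3 Hz, attenuated with severity
    a_neck = 0.010 * s * g["neck_2_4hz_gain"] * params.amp_jitter["neck"]
    pos["nose"] = np.stack(
        [msx + a_neck * np.sin(2 * np.pi * 3.0 * t + params.phase), (sh_y - 0.07 * s) + 0 * t],
        axis=1,
    )

    # legs: ankle separation oscillates at stride frequency (amplitude scales
    # with severity); both lower legs stretch in phase (modulation depth
    # shrinks with severity) so leg raise stays flat.
    upper, lower0 = 0.13 * s, 0.13 * s
    a_sep = 0.015 * s * g["ankle_sep_var_gain"] * params.amp_jitter["ankle_sep"]
    half_sep = hw + 0.01 * s + a_sep * np.sin(w_stride * t + params.phase)
    stretch = (0.18 * g["hip_ankle_var_gain"] * params.amp_jitter["leg_stretch"]
               * np.sin(w_stride * t + params.phase + 0.8))
    lower = lower0 * (1.0 + stretch)
    knee_osc = 0.004 * np.sin(2 * np.pi * 0.5 * t + 1.1)
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        hip = pos[f"{side}_hip"]
        knee = np.stack([hip[:, 0] + sgn * 0.01 * s + knee_osc, hip[:, 1] + upper], axis=1)
        ankle = np.stack([cx + sgn * half_sep, knee[:, 1] + lower], axis=1)
        pos[f"{side}_knee"] = knee
        pos[f"{side}_ankle"] = ankle

    # arms: rigid straight arm rotating about the shoulder so the
    # wrist-shoulder distance stays constant while the lateral angle carries
    # a stride fundamental, a 5 Hz component (down with severity) and a
    # 0.7 Hz drift (up with severity).
    arm_len = 0.11 * s
    alpha = (
        np.deg2rad(14.0)
        + np.deg2rad(5.0) * np.sin(w_stride * t + params.phase)
        + np.deg2rad(3.0) * g["armswing_highfreq_gain"] * params.amp_jitter["arm_hf"]
        * np.sin(2 * np.pi * 5.0 * t)
        + np.deg2rad(4.0) * g["armswing_drift_gain"] * params.amp_jitter["arm_drift"]
        * np.sin(2 * np.pi * 0.7 * t + 0.4)
    )
    # keep the arm lateral of the hip so the facing rule holds on clean frames
    alpha = np.clip(alpha, np.deg2rad(1.0), np.deg2rad(85.0))
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        sh = pos[f"{side}_shoulder"]
        dx = sgn * np.sin(alpha) * arm_len
        dy = np.cos(alpha) * arm_len
        pos[f"{side}_elbow"] = np.stack([sh[:, 0] + dx, sh[:, 1] + dy], axis=1)
        pos[f"{side}_wrist"] = np.stack([sh[:, 0] + 2 * dx, sh[:, 1] + 2 * dy], axis=1)

    coords = np.stack([pos[name] for name in BODY_LANDMARKS], axis=1)
    coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return LandmarkSeries(
        recording_id=recording_id,
        subject_id=subject_id,
        modality="body",
        med_state=med_state,
        fps=fps,
        landmark_names=list(BODY_LANDMARKS),
        coords=coords,
    )


def simulate_tapping(
    params: SubjectParams,
    theta: float,
    duration_s: float,
    fps: float,
    seed: int,
    effects: SeverityEffects | None = None,
    noise_sd: float = 0.002,
    recording_id: str = "tap",
    subject_id: str = "s0",
    med_state: str = "off",
) -> LandmarkSeries:
    """Two-hand tapping recording; the active hand is raised throughout."""
    effects = effects or SeverityEffects()
    g = effects.at(theta)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    s = params.scale
    active = params.active_hand
    resting = "right" if active == "left" else "left"

    tap_freq = params.tap_freq * g["tap_speed_gain"]
    a_tap = 0.060 * s * g["tap_amplitude_gain"] * params.amp_jitter["tap_amp"]
    a_jerk = 0.006 * s * g["tap_jerk_4_6hz_gain"] * params.amp_jitter["tap_jerk"]
    tap_dist = (
        0.015 * s
        + a_tap * 0.5 * (1 + np.sin(2 * np.pi * tap_freq * t + params.phase))
        + a_jerk * np.sin(2 * np.pi * 5.0 * t)
    )
    a_pinky = 0.008 * s * g["pinkie_comovement_gain"] * params.amp_jitter["pinky"]
    pinky_ext = 0.05 * s + a_pinky * np.sin(2 * np.pi * 2.0 * t + 0.7)

    pos: dict[str, np.ndarray] = {}
    # active hand raised: fingertips above the wrist (y-down)
    wx, wy = 0.55, 0.45
    pos[f"{active}_wrist"] = np.stack([wx + 0 * t, wy + 0 * t], axis=1)
    pos[f"{active}_index_mcp"] = np.stack([wx + 0.02 * s + 0 * t, wy - 0.075 * s + 0 * t], axis=1)
    pos[f"{active}_pinky_mcp"] = np.stack([wx - 0.02 * s + 0 * t, wy - 0.075 * s + 0 * t], axis=1)
    index_tip = np.stack([wx + 0.03 * s + 0 * t, wy - 0.14 * s + 0 * t], axis=1)
    pos[f"{active}_index_tip"] = index_tip
    thumb_dir = np.array([-np.sqrt(0.5), np.sqrt(0.5)])  # fixed unit direction
    pos[f"{active}_thumb_tip"] = index_tip + tap_dist[:, None] * thumb_dir[None, :]
    pos[f"{active}_middle_tip"] = np.stack(
        [wx + 0.01 * s + 0 * t, wy - 0.15 * s + 0 * t], axis=1)
    pos[f"{active}_ring_tip"] = np.stack(
        [wx - 0.01 * s + 0 * t, wy - 0.15 * s + 0 * t], axis=1)
    pinky_dir = np.array([-0.35, -1.0])
    pinky_dir = pinky_dir / np.linalg.norm(pinky_dir)
    pos[f"{active}_pinky_tip"] = (
        np.stack([wx - 0.02 * s + 0 * t, wy - 0.075 * s + 0 * t], axis=1)
        + pinky_ext[:, None] * pinky_dir[None, :]
    )

    # resting hand lowered and static: fingertips below the wrist
    rx, ry = 0.30, 0.70
    pos[f"{resting}_wrist"] = np.stack([rx + 0 * t, ry + 0 * t], axis=1)
    for name, (ox, oy) in {
        "thumb_tip": (0.04, 0.05), "index_tip": (0.03, 0.12), "middle_tip": (0.01, 0.13),
        "ring_tip": (-0.01, 0.13), "pinky_tip": (-0.03, 0.11),
        "index_mcp": (0.02, 0.075), "pinky_mcp": (-0.02, 0.075),
    }.items():
        pos[f"{resting}_{name}"] = np.stack(
            [rx + ox * s + 0 * t, ry + oy * s + 0 * t], axis=1)

    names = [f"{h}_{lm}" for h in ("left", "right") for lm in HAND_LANDMARKS]
    coords = np.stack([pos[name] for name in names], axis=1)
    coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return LandmarkSeries(
        recording_id=recording_id,
        subject_id=subject_id,
        modality="hand",
        med_state=med_state,
        fps=fps,
        landmark_names=names,
        coords=coords,
    )


def _place_events(
    n_frames: int, fps: float, events: list[tuple[str, float]], min_gap_s: float, rng
) -> list[tuple[str, int, int]]:
    """Place events in equal slots with clean gaps between and around them."""
    gap = int(round(min_gap_s * fps))
    k = len(events)
    usable = n_frames - 2 * gap
    slot = usable // k
    max_len = max(int(round(d * fps)) for _, d in events) + gap
    if usable <= 0 or slot < max_len:
        raise ValueError(
            f"recording too short for {k} artifact events with {min_gap_s} s gaps"
        )
    order = rng.permutation(k)
    placed: list[tuple[str, int, int]] = []
    for i, j in enumerate(order):
        kind, dur_s = events[j]
        length = max(int(round(dur_s * fps)), 1)
        jitter = int(rng.integers(0, max(slot - length - gap, 1)))
        start = gap + i * slot + jitter
        placed.append((kind, start, start + length))
    return sorted(placed, key=lambda e: e[1])


def inject_artifacts(
    series: LandmarkSeries, spec: ArtifactSpec, seed: int
) -> tuple[LandmarkSeries, list[dict]]:
    """Inject tracking artifacts targeted at the validity filters.

    Returns the modified series and an event log of (kind, start, end).
    """
    events = spec.events(series.modality)
    if not events:
        return series, []
    rng = np.random.default_rng(seed)
    placed = _place_events(series.frames, series.fps, events, spec.min_gap_s, rng)
    coords = series.coords.copy()
    validity = series.validity.copy()
    names = series.landmark_names
    for kind, start, end in placed:
        sl = slice(start, end)
        if kind == "dropout":
            validity[sl] = False
        elif kind == "flicker":
            li, ri = names.index("left_shoulder"), names.index("right_shoulder")
            # frame-wise swap of shoulder x creates rapid zero crossings
            frames = np.arange(start, end)
            swap = frames[frames % 2 == 0]
            lx = coords[swap, li, 0].copy()
            coords[swap, li, 0] = coords[swap, ri, 0]
            coords[swap, ri, 0] = lx
        elif kind == "crouch":
            for side in ("left", "right"):
                ki, ai = names.index(f"{side}_knee"), names.index(f"{side}_ankle")
                vec = coords[sl, ai, :] - coords[sl, ki, :]
                coords[sl, ai, :] = coords[sl, ki, :] + vec * 2.6  # beyond the 2x rule
        elif kind == "both_raised":
            hands = series.hands
            if len(hands) == 2:
                # find the hand whose index sits below its wrist and raise it
                for hand in hands:
                    ii = names.index(f"{hand}_index_tip")
                    wi = names.index(f"{hand}_wrist")
                    below = coords[sl, ii, 1] > coords[sl, wi, 1]
                    rows = np.arange(start, end)[below]
                    coords[rows, ii, 1] = coords[rows, wi, 1] - 0.10
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
    from dataclasses import replace

    log = [{"kind": k, "start": int(s), "end": int(e)} for k, s, e in placed]
    return replace(series, coords=coords, validity=validity), log


def generate_cohort(
    cfg: SyntheticCohortConfig, out_dir: str | Path
) -> dict:
    """Write landmark CSVs + sidecars, a manifest, and a ground-truth record.

    Severity groups are assigned deterministically (first mild, then severe by
    ``fraction_severe``); UPDRS-III scores are drawn from [10, 28] (mild) and
    [36, 60] (severe) so a fixed threshold of 32 reproduces the groups.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_severe = int(round(cfg.n_subjects * cfg.fraction_severe))
    n_mild = cfg.n_subjects - n_severe
    manifest_rows = []
    truth: dict = {
        "seed": cfg.seed,
        "effects": asdict(cfg.effects),
        "theta": {},
        "planted_patterns": SeverityEffects.planted_patterns(),
        "artifact_logs": {},
        "recordings": [],
    }
    for i in range(cfg.n_subjects):
        subject_id = f"sub{i:03d}"
        severe = i >= n_mild
        theta = cfg.theta_severe if severe else cfg.theta_mild
        rng = np.random.default_rng([cfg.seed, 2000 + i])
        score = float(rng.uniform(36, 60)) if severe else float(rng.uniform(10, 28))
        params = _subject_params(cfg, i)
        truth["theta"][subject_id] = theta
        manifest_rows.append({
            "subject_id": subject_id, "med_state": "off",
            "updrs3": round(score, 1), "updrs1": "", "updrs2": "",
            "hoehn_yahr": "", "moca": "",
            "age": int(rng.integers(55, 80)),
            "sex": str(rng.choice(["M", "F"])),
            "handedness": "R",
            "diagnosis": "PD",
        })
        for rec in range(cfg.recordings_per_subject):
            for mod_idx, (modality, simulate) in enumerate(
                (("body", simulate_gait), ("hand", simulate_tapping))
            ):
                rec_id = f"{subject_id}_{modality}{rec}"
                sim_seed = int(
                    np.random.default_rng([cfg.seed, 3000 + i, rec, mod_idx])
                    .integers(0, 2**31)
                )
                series = simulate(
                    params, theta, cfg.duration_s, cfg.fps, sim_seed,
                    effects=cfg.effects, noise_sd=cfg.noise_sd,
                    recording_id=rec_id, subject_id=subject_id, med_state="off",
                )
                series, log = inject_artifacts(series, cfg.artifacts, sim_seed + 1)
                write_landmark_series(series, out_dir / f"{rec_id}.csv")
                truth["artifact_logs"][rec_id] = log
                truth["recordings"].append(rec_id)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
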