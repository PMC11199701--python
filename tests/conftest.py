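import numpy as np
import pytest

from kinemetrix.io import BODY_LANDMARKS, HAND_LANDMARKS, LandmarkSeries
from kinemetrix.preprocessing import Segment
from kinemetrix.simulate import (
    ArtifactSpec,
    SubjectParams,
    SyntheticCohortConfig,
    generate_cohort,
    simulate_gait,
    simulate_tapping,
)


def make_body_series(
    coords_fn=None, frames=150, fps=30.0, recording_id="rec1", subject_id="subA",
    med_state="off",
):
    """A standing, forward-facing stick figure; coords_fn may perturb it."""
    pos = {
        "nose": (0.50, 0.28),
        "left_shoulder": (0.42, 0.35), "right_shoulder": (0.58, 0.35),
        "left_elbow": (0.38, 0.45), "right_elbow": (0.62, 0.45),
        "left_wrist": (0.36, 0.55), "right_wrist": (0.64, 0.55),
        "left_hip": (0.44, 0.55), "right_hip": (0.56, 0.55),
        "left_knee": (0.44, 0.68), "right_knee": (0.56, 0.68),
        "left_ankle": (0.44, 0.81), "right_ankle": (0.56, 0.81),
    }
    coords = np.empty((frames, 13, 2))
    for j, name in enumerate(BODY_LANDMARKS):
        coords[:, j, 0] = pos[name][0]
        coords[:, j, 1] = pos[name][1]
    if coords_fn is not None:
        coords = coords_fn(coords)
    return LandmarkSeries(
        recording_id=recording_id, subject_id=subject_id, modality="body",
        med_state=med_state, fps=fps, landmark_names=list(BODY_LANDMARKS),
        coords=coords,
    )


def make_hand_series(frames=150, fps=30.0, raised="left", both_raised=False,
                     recording_id="rec_h", subject_id="subA"):
    """Two-hand series with one hand raised (index above wrist, y-down)."""
    names = [f"{h}_{lm}" for h in ("left", "right") for lm in HAND_LANDMARKS]
    coords = np.empty((frames, 16, 2))
    base = {
        "wrist": (0.0, 0.0), "thumb_tip": (0.05, -0.08), "index_tip": (0.03, -0.14),
        "middle_tip": (0.01, -0.15), "ring_tip": (-0.01, -0.15),
        "pinky_tip": (-0.03, -0.12), "index_mcp": (0.02, -0.08),
        "pinky_mcp": (-0.02, -0.08),
    }
    for j, name in enumerate(names):
        hand, lm = name.split("_", 1)
        ox, oy = (0.55, 0.45) if hand == raised else (0.30, 0.70)
        dx, dy = base[lm]
        if hand != raised and not both_raised:
            dy = -dy  # fingers below the wrist: lowered hand
        coords[:, j, 0] = ox + dx
        coords[:, j, 1] = oy + dy
    return LandmarkSeries(
        recording_id=recording_id, subject_id=subject_id, modality="hand",
        med_state="off", fps=fps, landmark_names=names, coords=coords,
    )


def make_segment(series, active_hand=None, segment_id="seg0"):
    return Segment(
        segment_id=segment_id, recording_id=series.recording_id,
        start_frame=0, end_frame=series.frames, series=series,
        active_hand=active_hand,
    )


@pytest.fixture()
def body_series():
    return make_body_series()


@pytest.fixture()
def hand_series():
    return make_hand_series()


@pytest.fixture(scope="session")
def subject_params():
    return SubjectParams(
        scale=1.0, stride_freq=0.9, tap_freq=2.5, active_hand="right", phase=0.3
    )


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small simulated cohort with every artifact type, reused across tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SyntheticCohortConfig(
        n_subjects=8, duration_s=25.0, seed=7,
        artifacts=ArtifactSpec(n_dropout=1, n_flicker=1, n_crouch=1, n_both_raised=1),
    )
    truth = generate_cohort(cfg, out)
    return out, cfg, truth
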