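import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinemetrix.preprocessing import (
    SegmentationConfig,
    SmoothingConfig,
    body_validity_mask,
    dilate_invalid,
    flicker_mask,
    gaussian_kernel,
    gaussian_smooth,
    halo_radius,
    hand_validity_mask,
    preprocess_recording,
    segment,
)

from conftest import make_body_series, make_hand_series


class TestGaussianSmooth:
    def test_kernel_weights_against_brute_force(self):
        # independent evaluation of exp(-k^2 / (2 sigma^2)), k = -2..2
        k = np.arange(-2, 3)
        expected = np.exp(-(k**2) / (2 * 0.5**2))
        expected = expected / expected.sum()
        np.testing.assert_allclose(gaussian_kernel(5, 0.5), expected, atol=1e-12)
        assert gaussian_kernel(5, 0.5)[2] == pytest.approx(0.7866, abs=1e-4)

    def test_constant_preserved(self):
        series = make_body_series(frames=5)
        out = gaussian_smooth(series)
        np.testing.assert_allclose(out.coords, series.coords, atol=1e-12)

    def test_unit_impulse_center_weight(self):
        def bump(c):
            c[4, 0, 0] += 1.0
            return c

        series = make_body_series(coords_fn=bump, frames=9)
        out = gaussian_smooth(series)
        delta = out.coords[:, 0, 0] - make_body_series(frames=9).coords[:, 0, 0]
        # interior response equals the kernel; center weight ~0.7866
        np.testing.assert_allclose(delta[2:7], gaussian_kernel(5, 0.5), atol=1e-12)
        assert delta[4] == pytest.approx(0.7866, abs=1e-4)

    def test_linear_ramp_interior_unchanged(self):
        def ramp(c):
            c[:, :, 0] += np.linspace(0, 1, c.shape[0])[:, None]
            return c

        series = make_body_series(coords_fn=ramp, frames=50)
        out = gaussian_smooth(series)
        np.testing.assert_allclose(
            out.coords[2:-2, :, 0], series.coords[2:-2, :, 0], atol=1e-12
        )

    def test_mean_preserved_on_stationary_series(self):
        rng = np.random.default_rng(0)
        series = make_body_series(
            coords_fn=lambda c: c + rng.normal(0, 0.01, c.shape), frames=3000
        )
        out = gaussian_smooth(series)
        before = series.coords[2:-2, 0, 0].mean()
        after = out.coords[2:-2, 0, 0].mean()
        assert after == pytest.approx(before, abs=1e-6)

    def test_validity_passthrough(self):
        series = make_body_series(frames=10)
        series.validity[3] = False
        out = gaussian_smooth(series)
        np.testing.assert_array_equal(out.validity, series.validity)


class TestBodyValidity:
    def _with_leg_ratio(self, ratio):
        def shift(c):
            # lower leg vertical length is 0.13; upper leg is 0.13
            c[:, 11, 1] = c[:, 9, 1] + 0.13 * ratio  # left ankle below left knee
            c[:, 12, 1] = c[:, 10, 1] + 0.13 * ratio
            return c

        return make_body_series(coords_fn=shift)

    def test_valid_when_ratio_below_two(self):
        assert body_validity_mask(self._with_leg_ratio(1.9)).all()

    def test_invalid_when_ratio_above_two(self):
        assert not body_validity_mask(self._with_leg_ratio(2.1)).any()

    def test_ratio_exactly_two_counts_as_standing(self):
        assert body_validity_mask(self._with_leg_ratio(2.0)).all()

    def test_same_side_wrists_invalid(self):
        def shift(c):
            c[:, 5, 0] = c[:, 7, 0] + 0.05  # left wrist right of left hip
            return c

        assert not body_validity_mask(make_body_series(coords_fn=shift)).any()

    def test_wrong_modality(self, hand_series):
        with pytest.raises(ValueError, match="body"):
            body_validity_mask(hand_series)


class TestFlickerMask:
    def test_alternating_sign_flags_the_second(self):
        def flip(c):
            frames = np.arange(c.shape[0])
            zone = (frames >= 60) & (frames < 90)
            swap = zone & (frames % 2 == 0)
            left = c[swap, 1, 0].copy()
            c[swap, 1, 0] = c[swap, 2, 0]
            c[swap, 2, 0] = left
            return c

        series = make_body_series(coords_fn=flip, frames=300)
        mask = flicker_mask(series)
        assert mask[60:90].all()
        assert not mask[:40].any() and not mask[110:].any()

    def test_constant_sign_no_flags(self, body_series):
        assert not flicker_mask(body_series).any()

    def test_single_crossing_not_flagged(self):
        def turn(c):
            left = c[150:, 1, 0].copy()
            c[150:, 1, 0] = c[150:, 2, 0]
            c[150:, 2, 0] = left
            return c

        series = make_body_series(coords_fn=turn, frames=300)
        assert not flicker_mask(series).any()  # 1 crossing < 3

    def test_brute_force_window_census(self):
        rng = np.random.default_rng(5)
        d_sign = rng.choice([-1.0, 1.0], size=120)

        def impose(c):
            c[:, 1, 0] = 0.5 - 0.08 * d_sign
            c[:, 2, 0] = 0.5 + 0.08 * d_sign
            return c

        series = make_body_series(coords_fn=impose, frames=120)
        cfg = SegmentationConfig()
        mask = flicker_mask(series, cfg)
        # oracle: frame f flagged iff some window [a, a+w) covering f has >= 3
        # crossings, counted by direct enumeration
        d = series.x("left_shoulder") - series.x("right_shoulder")
        w = int(round(cfg.flicker_window_s * series.fps))
        crossings = np.sign(d[:-1]) * np.sign(d[1:]) < 0
        expected = np.zeros(len(d), dtype=bool)
        for a in range(len(d) - w + 1):
            if crossings[a : a + w - 1].sum() >= cfg.flicker_min_crossings:
                expected[a : a + w] = True
        np.testing.assert_array_equal(mask, expected)


class TestHandValidity:
    def test_one_raised_valid_active_left(self):
        valid, active = hand_validity_mask(make_hand_series(raised="left"))
        assert valid.all()
        assert (active == "left").all()

    def test_both_raised_invalid(self):
        valid, _ = hand_validity_mask(make_hand_series(both_raised=True))
        assert not valid.any()

    def test_single_right_hand(self, tmp_path):
        two = make_hand_series(raised="right")
        names = [n for n in two.landmark_names if n.startswith("right_")]
        idx = [two.landmark_names.index(n) for n in names]
        from dataclasses import replace

        single = replace(two, landmark_names=names, coords=two.coords[:, idx, :])
        valid, active = hand_validity_mask(single)
        assert valid.all()
        assert (active == "right").all()

    def test_wrong_modality(self, body_series):
        with pytest.raises(ValueError, match="hand"):
            hand_validity_mask(body_series)


class TestDilateInvalid:
    def test_single_invalid_frame_halo(self):
        assert halo_radius(0.333, 30.0) == 10
        mask = np.ones(100, dtype=bool)
        mask[50] = False
        out = dilate_invalid(mask, fps=30.0)
        assert not out[40:61].any()
        assert out[:40].all() and out[61:].all()

    def test_union_of_halos(self):
        mask = np.ones(120, dtype=bool)
        mask[[50, 55]] = False
        out = dilate_invalid(mask, fps=30.0)
        assert not out[40:66].any()
        assert out[:40].all() and out[66:].all()

    def test_all_valid_unchanged(self):
        mask = np.ones(50, dtype=bool)
        np.testing.assert_array_equal(dilate_invalid(mask, 30.0), mask)

    def test_proportional_to_fps(self):
        assert halo_radius(0.333, 60.0) == 20
        assert halo_radius(0.333, 15.0) == 5

    @given(
        invalid=st.lists(st.integers(0, 99), max_size=12),
        extra=st.lists(st.integers(0, 99), max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_matches_halo_oracle(self, invalid, extra):
        mask = np.ones(100, dtype=bool)
        mask[invalid] = False
        out = dilate_invalid(mask, 30.0)
        # brute-force oracle: frame i invalid iff some invalid j with |i-j| <= r
        r = halo_radius(0.333, 30.0)
        expected = np.array([
            all(abs(i - j) > r for j in invalid) for i in range(100)
        ])
        np.testing.assert_array_equal(out, expected)
        mask2 = mask.copy()
        mask2[extra] = False
        out2 = dilate_invalid(mask2, 30.0)
        assert not np.any(~out & out2)  # monotone: superset of invalids


class TestSegment:
    def _run(self, seconds, fps=30.0, frames_total=None):
        n = int(seconds * fps)
        total = frames_total or n
        series = make_body_series(frames=total, fps=fps)
        valid = np.zeros(total, dtype=bool)
        valid[:n] = True
        return segment(series, valid)

    def test_short_run_discarded(self):
        assert self._run(2.9) == []

    def test_seven_second_run_kept_whole(self):
        segs = self._run(7.0)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(7.0)

    def test_ten_second_run_split_in_two(self):
        segs = self._run(10.0)
        assert len(segs) == 2
        assert [s.duration_s for s in segs] == pytest.approx([5.0, 5.0])

    def test_twenty_second_run_split_in_three(self):
        segs = self._run(20.0)
        assert len(segs) == 3  # ceil(20 / 8)
        assert sum(s.n_frames for s in segs) == 600
        durations = [s.duration_s for s in segs]
        assert max(durations) - min(durations) <= 1 / 30.0  # near-equal pieces

    def test_all_segments_within_bounds_no_invalid(self):
        rng = np.random.default_rng(11)
        total = 3000
        series = make_body_series(frames=total)
        valid = rng.random(total) > 0.01
        valid = dilate_invalid(valid, series.fps)
        for seg in segment(series, valid):
            assert 3.0 <= seg.duration_s <= 8.0
            assert valid[seg.start_frame : seg.end_frame].all()

    def test_ids_deterministic_and_ordered(self):
        segs = self._run(20.0)
        assert [s.segment_id for s in segs] == ["rec1_s000", "rec1_s001", "rec1_s002"]
        assert sorted(s.start_frame for s in segs) == [s.start_frame for s in segs]


class TestPreprocessRecording:
    def test_clean_gait_loses_no_frames(self, subject_params):
        from kinemetrix.simulate import simulate_gait

        series = simulate_gait(subject_params, 0.5, 20.0, 30.0, seed=0)
        segs = preprocess_recording(series)
        assert sum(s.n_frames for s in segs) >= 0.9 * series.frames

    def test_dropout_event_separated_windows(self):
        # artifact events separated by > 2*halo + min_duration of clean signal
        series = make_body_series(frames=900)  # 30 s
        series.validity[300] = False
        series.validity[600] = False
        segs = preprocess_recording(series)
        # clean stretches: [0, 290), [311, 590), [611, 900) -> all >= 3 s
        assert len(segs) >= 3
        covered = sum(s.n_frames for s in segs)
        assert covered >= 900 - 2 * (2 * 10 + 1) - 10
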