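"""Generator contracts: geometry, determinism, embedded ground truth."""

import math

import numpy as np
import pytest
from scipy import stats

from headgaze import gaze, synthdata
from headgaze.synthdata import EyeImageSpec, TrajectorySpec


class TestEyeImage:
    def test_mask_is_exactly_the_ellipse(self):
        spec = EyeImageSpec(pupil_center=(40.0, 50.0), pupil_axes=(12.0, 8.0),
                            pupil_angle=0.4, noise_sd=0.0)
        _, mask = synthdata.gen_eye_image(spec)
        rr, cc = np.mgrid[0:96, 0:96].astype(float)
        c, s = math.cos(0.4), math.sin(0.4)
        u = (cc - 50.0) * c + (rr - 40.0) * s
        v = -(cc - 50.0) * s + (rr - 40.0) * c
        inside = (u / 12.0) ** 2 + (v / 8.0) ** 2 <= 1.0
        assert np.array_equal(mask, inside)

    def test_seeded_determinism(self):
        spec = EyeImageSpec(noise_sd=4.0, seed=7, illumination_gradient=(0.3, -0.2))
        img1, m1 = synthdata.gen_eye_image(spec)
        img2, m2 = synthdata.gen_eye_image(spec)
        assert np.array_equal(img1, img2) and np.array_equal(m1, m2)

    def test_corner_shadow_darker_than_pupil(self):
        # the failure mode for fixed-threshold detection: a shadow darker
        # than the pupil itself
        spec = EyeImageSpec(pupil_intensity=30.0,
                            shadow_blobs=(((4.0, 4.0), 10.0, 10.0),))
        img, mask = synthdata.gen_eye_image(spec)
        rr, cc = np.mgrid[0:96, 0:96].astype(float)
        shadow = (rr - 4) ** 2 + (cc - 4) ** 2 <= 100
        assert img[shadow].min() < img[mask].min()

    def test_out_of_bounds_pupil_rejected(self):
        spec = EyeImageSpec(pupil_center=(5.0, 48.0), pupil_axes=(14.0, 10.0))
        with pytest.raises(ValueError, match="pupil_center|pupil_axes"):
            synthdata.gen_eye_image(spec)

    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="dark-pupil"):
            synthdata.gen_eye_image(EyeImageSpec(pupil_intensity=150.0, iris_intensity=110.0))

    def test_batch_reproducible(self):
        a = synthdata.gen_eye_image_batch(5, seed=3)
        b = synthdata.gen_eye_image_batch(5, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestGazeTrajectory:
    def test_perfect_vor_gaze_constant(self):
        # gain 1, no shifts: the eye exactly cancels head drift, matched grids
        spec = TrajectorySpec(duration=10.0, eye_rate=90.0, head_rate=90.0,
                              vor_gain=1.0, shift_rate=1e-4,
                              measurement_noise_sd=0.0, seed=2)
        eye, head, truth = synthdata.gen_gaze_trajectory(spec)
        assert not truth.shift_intervals
        gaze_h = eye["eye_h_deg"].to_numpy() + head["head_yaw_deg"].to_numpy()
        assert np.ptp(gaze_h) < 1e-9

    def test_shift_count_in_poisson_band(self):
        # the generator thins a Poisson process with a refractory gap; the
        # count for this seed must land in the central 99% band of the
        # un-thinned Poisson(rate * duration) oracle
        spec = TrajectorySpec(duration=60.0, shift_rate=1.0, seed=11)
        _, _, truth = synthdata.gen_gaze_trajectory(spec)
        lo = stats.poisson.ppf(0.005, 60.0)
        hi = stats.poisson.ppf(0.995, 60.0)
        assert lo <= len(truth.shift_intervals) <= hi

    def test_eye_cap_and_remainder(self):
        # 30 deg gaze shift with a 20 deg eye ceiling: eye 20, head 10
        spec = TrajectorySpec(duration=30.0, amplitude_min=30.0, amplitude_max=30.0,
                              amplitude_mean=30.0, eye_saturation_amplitude=20.0, seed=4)
        _, _, truth = synthdata.gen_gaze_trajectory(spec)
        assert len(truth.shift_intervals) > 0
        assert np.allclose(np.abs(truth.amp_eye), 20.0)
        assert np.allclose(np.abs(truth.amp_head), 10.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_amplitude_conservation(self, seed):
        _, _, truth = synthdata.gen_gaze_trajectory(TrajectorySpec(duration=40.0, seed=seed))
        assert np.abs(truth.amp_eye + truth.amp_head - truth.amp_gaze).max() <= 1e-6

    def test_intervals_disjoint_sorted_within_duration(self):
        _, _, truth = synthdata.gen_gaze_trajectory(TrajectorySpec(duration=60.0, seed=5))
        iv = truth.shift_intervals
        assert all(a < b for a, b in iv)
        assert all(iv[i][1] < iv[i + 1][0] for i in range(len(iv) - 1))
        assert iv[0][0] >= 0 and iv[-1][1] <= 60.0

    def test_fixation_vor_slope_matches_gain(self):
        # OLS of eye on head velocity inside true fixations recovers -gain
        spec = TrajectorySpec(duration=60.0, vor_gain=0.8, measurement_noise_sd=0.0, seed=6)
        eye, head, truth = synthdata.gen_gaze_trajectory(spec)
        series = gaze.align_streams(eye, head)
        ve = np.diff(series.eye_h) * series.rate
        vh = np.diff(series.head_yaw) * series.rate
        tmid = series.t[:-1]
        sel = np.zeros(tmid.size, bool)
        for t0, t1 in truth.fixation_intervals:
            sel |= (tmid >= t0 + 0.05) & (tmid <= t1 - 0.05)
        slope = stats.linregress(vh[sel], ve[sel]).slope
        assert abs(-slope - 0.8) <= 0.02

    def test_conflicting_shift_rate_rejected(self):
        with pytest.raises(ValueError, match="refractory"):
            synthdata.gen_gaze_trajectory(TrajectorySpec(duration=10.0, shift_rate=10.0))

    def test_bitwise_reproducible(self):
        spec = TrajectorySpec(duration=20.0, measurement_noise_sd=0.1, seed=9)
        a = synthdata.gen_gaze_trajectory(spec)
        b = synthdata.gen_gaze_trajectory(spec)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        assert a[2].shift_intervals == b[2].shift_intervals


class TestLocomotionTrack:
    def test_qualifying_bout_in_truth(self):
        _, truth = synthdata.gen_locomotion_track(
            30.0, bouts=[(5.0, 15.0, 10.0)], head_height_cm=10.0)
        assert truth == [(5.0, 15.0)]

    def test_short_bout_excluded(self):
        # locomotion must exceed 3 s
        _, truth = synthdata.gen_locomotion_track(30.0, bouts=[(5.0, 7.0, 10.0)],
                                                  head_height_cm=10.0)
        assert truth == []

    def test_high_head_excluded(self):
        # head must stay below 18 cm
        _, truth = synthdata.gen_locomotion_track(30.0, bouts=[(5.0, 15.0, 10.0)],
                                                  head_height_cm=25.0)
        assert truth == []

    def test_slow_bout_excluded(self):
        _, truth = synthdata.gen_locomotion_track(30.0, bouts=[(5.0, 15.0, 4.0)],
                                                  head_height_cm=10.0)
        assert truth == []

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthdata.gen_locomotion_track(30.0, bouts=[(5.0, 15.0, 10.0), (14.0, 20.0, 8.0)])

    def test_speed_integrates_positions(self):
        track, _ = synthdata.gen_locomotion_track(
            20.0, rate=100.0, bouts=[(5.0, 15.0, 10.0)], jitter_sd=0.0, seed=1)
        xy = track[["x_cm", "y_cm"]].to_numpy()
        d = np.linalg.norm(xy[-1] - xy[0])
        assert d == pytest.approx(100.0, rel=0.02)  # 10 cm/s for 10 s


class TestSceneShapes:
    def test_square_is_four_segments_of_total_length_40(self):
        shapes = synthdata.gen_scene_shapes(
            "polygon", vertices=[(-5, -5), (5, -5), (5, 5), (-5, 5)])
        assert len(shapes) == 4
        total = sum(np.linalg.norm(p.coords[1] - p.coords[0]) for p in shapes)
        assert total == pytest.approx(40.0)

    def test_single_point(self):
        shapes = synthdata.gen_scene_shapes("point", position=(3.0, -2.0))
        assert len(shapes) == 1 and shapes[0].kind == "point"
        assert np.allclose(shapes[0].coords, [[3.0, -2.0]])

    def test_pursuit_speed_limit(self):
        with pytest.raises(ValueError, match="5 deg/s"):
            synthdata.gen_scene_shapes("pursuit_path", duration=5.0, speed=6.0)

    def test_pursuit_path_moves_at_requested_speed(self):
        path = synthdata.gen_scene_shapes("pursuit_path", duration=5.0, speed=3.0,
                                          rate=90.0, seed=0)
        steps = np.hypot(np.diff(path["x_deg"]), np.diff(path["y_deg"])) * 90.0
        assert np.allclose(steps, 3.0, atol=1e-9)

    def test_schedule_assigns_3s_on_3s_off(self):
        square = synthdata.gen_scene_shapes("polygon", vertices=[(0, 0), (1, 0), (1, 1)])
        point = synthdata.gen_scene_shapes("point", position=(0.0, 0.0))
        scene = synthdata.schedule_scene([square, point])
        assert all(p.active_interval == (0.0, 3.0) for p in scene[:3])
        assert scene[3].active_interval == (6.0, 9.0)
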