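"""Main sequence, VOR gain, rms stabilization, ApEn, locomotion, state stats."""

import math

import numpy as np
import pytest
from scipy import stats

from headgaze import gaze, kinematics, synthdata
from headgaze.gaze import ChannelKinematics, GazeEvent, GazeSeries
from headgaze.kinematics import BehaviorEpoch
from headgaze.synthdata import TrajectorySpec


def _series_from(eye, head, rate=90.0):
    eye = np.asarray(eye, float)
    head = np.asarray(head, float)
    n = eye.size
    return GazeSeries(t=np.arange(n) / rate, eye_h=eye, eye_v=np.zeros(n),
                      head_yaw=head, head_pitch=np.zeros(n), gaze_h=eye + head,
                      valid=np.ones(n, bool), rate=rate)


def _shift_event(t0=0.0, amp=10.0, vpeak=400.0, dur=0.05):
    kin = ChannelKinematics(amplitude=amp, peak_velocity=vpeak,
                            latency_to_peak=dur / 2, duration=dur)
    zero = ChannelKinematics(amplitude=0.0, peak_velocity=0.0,
                             latency_to_peak=0.0, duration=dur)
    return GazeEvent("gaze_shift", t0, t0 + dur,
                     {"gaze_h": kin, "eye_h": kin, "head_yaw": zero})


class TestMainSequence:
    def test_constructed_shift_row(self):
        table, binned, fit = kinematics.main_sequence([_shift_event()])
        row = table.iloc[0]
        assert row["gaze_amplitude_deg"] == pytest.approx(10.0)
        assert row["gaze_h_peak_velocity_dps"] == pytest.approx(400.0)
        assert row["gaze_h_latency_to_peak_s"] == pytest.approx(0.025)
        assert row["duration_s"] == pytest.approx(0.05)

    def test_rectification_by_shift_direction(self):
        kin = ChannelKinematics(amplitude=-10.0, peak_velocity=-400.0,
                                latency_to_peak=0.02, duration=0.05)
        ev = GazeEvent("gaze_shift", 0.0, 0.05,
                       {"gaze_h": kin, "eye_h": kin, "head_yaw": kin})
        table, _, _ = kinematics.main_sequence([ev])
        assert table.iloc[0]["gaze_amplitude_deg"] == pytest.approx(10.0)
        assert table.iloc[0]["eye_h_peak_velocity_dps"] == pytest.approx(400.0)

    def test_fixations_only_empty(self):
        ev = GazeEvent("gaze_fixation", 0.0, 1.0, {})
        table, binned, fit = kinematics.main_sequence([ev])
        assert table.empty and math.isnan(fit["plateau_dps"])

    def test_hinge_fit_recovers_synthetic_law(self):
        # velocities drawn exactly from the saturating law, no detector noise
        rng = np.random.default_rng(0)
        amps = rng.uniform(2.0, 60.0, 300)
        events = [
            _shift_event(t0=i, amp=a, vpeak=400.0 * min(a, 10.0) / 10.0)
            for i, a in enumerate(amps)
        ]
        _, _, fit = kinematics.main_sequence(events)
        assert fit["plateau_dps"] == pytest.approx(400.0, rel=0.02)
        assert fit["knee_deg"] == pytest.approx(10.0, abs=0.5)


class TestVorGain:
    def test_exact_compensation(self):
        rng = np.random.default_rng(1)
        head = np.cumsum(rng.normal(0, 0.05, 2000))
        series = _series_from(-0.9 * head, head)
        res = kinematics.vor_gain(series, [(0.0, series.t[-1])])
        assert res.gain == pytest.approx(0.9, abs=1e-9)
        assert res.se < 1e-9

    def test_zero_head_velocity_unidentifiable(self):
        series = _series_from(np.zeros(200), np.zeros(200))
        with pytest.raises(ValueError, match="unidentifiable|variance"):
            kinematics.vor_gain(series, [(0.0, 2.0)])

    def test_too_few_samples_rejected(self):
        series = _series_from(np.zeros(200), np.zeros(200))
        with pytest.raises(ValueError, match="fixation samples"):
            kinematics.vor_gain(series, [(0.0, 0.05)])

    def test_recovery_from_generator(self):
        spec = TrajectorySpec(duration=60.0, vor_gain=0.8, eye_velocity_noise_sd=0.5,
                              measurement_noise_sd=0.0, seed=21)
        eye, head, truth = synthdata.gen_gaze_trajectory(spec)
        series = gaze.align_streams(eye, head)
        res = kinematics.vor_gain(series, truth.fixation_intervals)
        assert abs(res.gain - 0.8) <= max(0.02, 3 * res.se)


class TestRmsStabilization:
    def test_constant_channel_zero(self):
        series = _series_from(np.zeros(300), np.full(300, 4.0))
        per, summary = kinematics.rms_stabilization(series, [(0.0, 3.0)], "head_yaw")
        assert per == [0.0]

    def test_sinusoid_head_compensated_gaze(self):
        # head A sin(wt), eye = -head: head rms A/sqrt(2), gaze rms 0
        t = np.arange(0, 100.0, 1 / 90)
        head = 2.0 * np.sin(2 * np.pi * 1.0 * t)
        series = _series_from(-head, head)
        epochs = [(0.0, 100.0)]
        _, s_head = kinematics.rms_stabilization(series, epochs, "head_yaw")
        _, s_gaze = kinematics.rms_stabilization(series, epochs, "gaze_h")
        assert s_head["pooled_rms_deg"] == pytest.approx(2.0 / np.sqrt(2), rel=0.01)
        assert s_gaze["pooled_rms_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_gaze_more_stable_than_head_for_good_vor(self):
        for g in (0.6, 0.8, 1.0):
            spec = TrajectorySpec(duration=30.0, vor_gain=g,
                                  measurement_noise_sd=0.0, seed=int(10 * g))
            eye, head, truth = synthdata.gen_gaze_trajectory(spec)
            series = gaze.align_streams(eye, head)
            fix = [iv for iv in truth.fixation_intervals if iv[1] - iv[0] > 0.2]
            _, s_gaze = kinematics.rms_stabilization(series, fix, "gaze_h")
            _, s_head = kinematics.rms_stabilization(series, fix, "head_yaw")
            assert s_gaze["pooled_rms_deg"] <= s_head["pooled_rms_deg"]

    def test_state_pooling(self):
        series = _series_from(np.zeros(1800), np.zeros(1800))
        behavior = [BehaviorEpoch("locomotion", 0.0, 10.0),
                    BehaviorEpoch("stationary", 10.0, 20.0)]
        _, summary = kinematics.rms_stabilization(
            series, [(1.0, 2.0), (12.0, 13.0)], "gaze_h", behavior)
        assert set(summary["by_state"]) == {"locomotion", "stationary"}


def apen_bruteforce(x, m, r):
    """O(n^2) double-loop reference: Pincus ApEn with self-matches."""
    x = np.asarray(x, float)
    n = x.size
    rr = r * np.std(x)

    def phi(mm):
        nn = n - mm + 1
        logs = []
        for i in range(nn):
            c = 0
            for j in range(nn):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= rr:
                    c += 1
            logs.append(np.log(c / nn))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert kinematics.approximate_entropy(np.full(50, 3.0), 2, 0.2) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        x = rng.normal(size=n)
        assert kinematics.approximate_entropy(x, 2, 0.2) == apen_bruteforce(x, 2, 0.2)

    def test_white_noise_more_entropic_than_sinusoid(self):
        rng = np.random.default_rng(3)
        n = 300
        noise = rng.normal(0, 1, n)
        sine = np.sqrt(2) * np.sin(2 * np.pi * np.arange(n) / 25)  # SD 1
        assert kinematics.approximate_entropy(noise) > kinematics.approximate_entropy(sine)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="r must be > 0"):
            kinematics.approximate_entropy(np.arange(50.0), 2, 0.0)
        with pytest.raises(ValueError, match="length"):
            kinematics.approximate_entropy(np.arange(10.0), 2, 0.2)


class TestClassifyLocomotion:
    RATE = 120.0

    def _run(self, bouts, head=10.0, duration=40.0):
        track, truth = synthdata.gen_locomotion_track(
            duration, rate=self.RATE, bouts=bouts, head_height_cm=head, seed=0)
        epochs = kinematics.classify_locomotion(
            track[["x_cm", "y_cm"]].to_numpy(), track["head_z_cm"].to_numpy(), self.RATE)
        return [e for e in epochs if e.label == "locomotion"], truth

    def test_qualifying_bout_recovered(self):
        loco, truth = self._run([(10.0, 20.0, 10.0)])
        assert len(loco) == 1 and truth == [(10.0, 20.0)]
        # boundary error within 2 samples + the low-pass transient
        tol = 2 / self.RATE + 0.5
        assert abs(loco[0].t_start - 10.0) <= tol
        assert abs(loco[0].t_end - 20.0) <= tol

    def test_short_bout_stays_stationary(self):
        loco, _ = self._run([(10.0, 12.0, 10.0)])
        assert loco == []

    def test_high_head_stays_stationary(self):
        loco, _ = self._run([(10.0, 20.0, 10.0)], head=25.0)
        assert loco == []

    def test_slow_bout_stays_stationary(self):
        loco, _ = self._run([(10.0, 20.0, 4.0)])
        assert loco == []

    def test_constant_position_single_stationary_epoch(self):
        epochs = kinematics.classify_locomotion(np.zeros((1200, 2)), np.full(1200, 10.0),
                                                self.RATE)
        assert len(epochs) == 1 and epochs[0].label == "stationary"

    def test_epochs_tile_session(self):
        track, _ = synthdata.gen_locomotion_track(
            60.0, rate=self.RATE, bouts=[(10.0, 20.0, 10.0), (35.0, 45.0, 12.0)],
            head_height_cm=10.0, seed=0)
        epochs = kinematics.classify_locomotion(
            track[["x_cm", "y_cm"]].to_numpy(), track["head_z_cm"].to_numpy(), self.RATE)
        assert epochs[0].t_start == 0.0
        for a, b in zip(epochs, epochs[1:]):
            assert a.t_end == b.t_start
        assert epochs[-1].t_end == pytest.approx(60.0, abs=1 / self.RATE)

    def test_mismatched_tracks_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kinematics.classify_locomotion(np.zeros((100, 2)), np.zeros(90), 120.0)


class TestShiftStatistics:
    def test_rate_counting(self):
        behavior = [BehaviorEpoch("locomotion", 0.0, 10.0),
                    BehaviorEpoch("stationary", 10.0, 20.0)]
        events = [_shift_event(t0=t) for t in np.linspace(0.5, 9.0, 10)]
        out = kinematics.shift_statistics(events, behavior)
        assert out["by_state"]["locomotion"]["rate_per_s"] == pytest.approx(1.0)
        assert out["by_state"]["stationary"]["rate_per_s"] == 0.0

    def test_no_shifts_all_rates_zero(self):
        behavior = [BehaviorEpoch("locomotion", 0.0, 10.0),
                    BehaviorEpoch("stationary", 10.0, 20.0)]
        out = kinematics.shift_statistics([], behavior)
        assert all(v["rate_per_s"] == 0.0 for v in out["by_state"].values())

    def test_poisson_rate_recovery_by_state(self):
        # locomotion shifts at 2/s vs stationary 1/s: recovered rates inside
        # the Poisson 95% interval oracle
        rng = np.random.default_rng(8)
        behavior = [BehaviorEpoch("locomotion", 0.0, 100.0),
                    BehaviorEpoch("stationary", 100.0, 200.0)]
        events = [_shift_event(t0=t) for t in np.sort(rng.uniform(0, 100, rng.poisson(200)))]
        events += [_shift_event(t0=t) for t in np.sort(rng.uniform(100, 200, rng.poisson(100)))]
        out = kinematics.shift_statistics(events, behavior)
        for state, lam in (("locomotion", 200), ("stationary", 100)):
            n = out["by_state"][state]["n_shifts"]
            assert stats.poisson.ppf(0.025, lam) <= n <= stats.poisson.ppf(0.975, lam)
        assert "rank_sum_tests" in out


class TestOccupancyMap:
    BOUNDS = ((0.0, 200.0), (0.0, 100.0))

    def test_single_point_single_bin(self):
        t = np.arange(100) / 10.0
        xy = np.full((100, 2), 50.0)
        grid, _, _, paths = kinematics.occupancy_map(
            t, xy, 10.0, [BehaviorEpoch("stationary", 0.0, 10.0)], self.BOUNDS)
        assert grid.sum() == 100 and (grid > 0).sum() == 1
        assert paths == []

    def test_grid_total_conservation(self):
        rng = np.random.default_rng(5)
        t = np.arange(1000) / 10.0
        xy = np.column_stack([rng.uniform(0, 200, 1000), rng.uniform(0, 100, 1000)])
        behavior = [BehaviorEpoch("stationary", 0.0, 50.0),
                    BehaviorEpoch("locomotion", 50.0, 100.0)]
        grid, _, _, paths = kinematics.occupancy_map(t, xy, 10.0, behavior, self.BOUNDS)
        n_stat = int(((t >= 0) & (t <= 50.0)).sum())
        assert grid.sum() == n_stat
        assert sum(len(p) for p in paths) == 1000 - n_stat

    def test_reflected_random_walk_uniform_on_coarse_bins(self):
        # a fast-mixing reflected walk approaches the uniform stationary
        # distribution; chi-square uniformity must not reject at alpha 0.001
        rng = np.random.default_rng(9)
        n = 8000
        raw = np.cumsum(rng.normal(0, 120.0, (n, 2)), axis=0) + [100.0, 50.0]
        xy = np.empty_like(raw)
        xy[:, 0] = 200.0 - np.abs(raw[:, 0] % 400.0 - 200.0)  # reflect into [0, 200]
        xy[:, 1] = 100.0 - np.abs(raw[:, 1] % 200.0 - 100.0)  # reflect into [0, 100]
        t = np.arange(n) / 10.0
        grid, _, _, _ = kinematics.occupancy_map(
            t, xy, 50.0, [BehaviorEpoch("stationary", 0.0, t[-1])], self.BOUNDS)
        chi2, p = stats.chisquare(grid.ravel())
        assert p > 0.001

    def test_outside_samples_warn_into_edge_bins(self):
        t = np.arange(10.0)
        xy = np.full((10, 2), -5.0)
        with pytest.warns(UserWarning, match="outside"):
            grid, _, _, _ = kinematics.occupancy_map(
                t, xy, 10.0, [BehaviorEpoch("stationary", 0.0, 10.0)], self.BOUNDS)
        assert grid.sum() == 10 and grid[0, 0] == 10


class TestEyePositionDistributions:
    def test_two_sd_span_recovers_sd(self):
        rng = np.random.default_rng(4)
        n = 2000
        eye = rng.normal(0, 2.5, n)
        series = _series_from(eye, np.zeros(n))
        events = [GazeEvent("gaze_fixation", 0.0, float(series.t[-1]), {})]
        out = kinematics.eye_position_distributions(series, events)
        assert out["eye_h"]["fixation"]["span_2sd_deg"] == pytest.approx(5.0, rel=0.05)
        assert out["eye_h"]["shift"]["n"] == 0

    def test_constant_position_zero_span(self):
        series = _series_from(np.full(200, 1.0), np.zeros(200))
        events = [GazeEvent("gaze_fixation", 0.0, float(series.t[-1]), {})]
        out = kinematics.eye_position_distributions(series, events)
        assert out["eye_h"]["fixation"]["span_2sd_deg"] == 0.0

    def test_splits_partition_valid_samples(self):
        n = 900
        series = _series_from(np.zeros(n), np.zeros(n))
        t_half = float(series.t[n // 2])
        events = [GazeEvent("gaze_fixation", 0.0, t_half, {}),
                  GazeEvent("gaze_shift", t_half + 1 / 90, float(series.t[-1]), {})]
        out = kinematics.eye_position_distributions(series, events)
        total = out["eye_h"]["fixation"]["n"] + out["eye_h"]["shift"]["n"]
        assert total == n

    def test_too_few_samples_rejected(self):
        series = _series_from(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError, match="valid samples"):
            kinematics.eye_position_distributions(series, [])


class TestStabilityReport:
    def test_report_assembles(self):
        spec = TrajectorySpec(duration=30.0, seed=13, measurement_noise_sd=0.05)
        eye, head, _ = synthdata.gen_gaze_trajectory(spec)
        series = gaze.align_streams(eye, head)
        events = gaze.segment_gaze(series)
        report = kinematics.stability_report(series, events)
        assert report["gaze_rms"]["pooled_rms_deg"] <= report["head_rms"]["pooled_rms_deg"]
        assert 0.5 <= report["vor_gain"]["gain"] <= 1.2
        assert "eye_h" in report["approximate_entropy"]
        assert report["apen_params"]["on"] == "position"
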