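"""Per-trial kinematics: calibration, pitch, phase marks, rotational
velocity, COM derivatives, steady states, wingbeat statistics, landing
speed, and the frame-invariance properties of the whole chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylloflight.kinematics import (KinematicsConfig, PhaseMarks, PitchProfile,
                                     analyze_trial, calibrate_scale, com_trajectory,
                                     compute_pitch, landing_speed, rotational_velocity,
                                     segment_phases, steady_velocities, verify_gravity,
                                     wingbeat_stats, _savgol)
from phylloflight.synthetic import (TrajectoryParams, simulate_ball_drop,
                                    simulate_drop_flight)
from phylloflight.track import TrajectoryTrack


def _simple_track(head, abd=None, wing=None, fps=500.0, calibrated=True):
    n = len(head)
    return TrajectoryTrack(t=np.arange(n) / fps, head=np.asarray(head, float),
                           abd=None if abd is None else np.asarray(abd, float),
                           wing=None if wing is None else np.asarray(wing, float),
                           fps=fps, units_calibrated=calibrated)


class TestCalibration:
    def test_scale_bar_maps_pixels_to_metres(self):
        head = np.tile([100.0, 200.0], (20, 1))
        trk = _simple_track(head, abd=head + [10, 0], calibrated=False)
        cal = calibrate_scale(trk, bar_len_px=500.0, bar_len_true=0.5)
        # 500 px = 0.5 m -> 1 px = 1 mm
        np.testing.assert_allclose(cal.head[0], [0.1, 0.2])
        assert cal.units_calibrated

    def test_zero_bar_length_raises(self):
        trk = _simple_track(np.zeros((20, 2)), calibrated=False)
        with pytest.raises(ValueError):
            calibrate_scale(trk, 0.0, 0.5)

    def test_double_calibration_refused(self):
        trk = _simple_track(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="already calibrated"):
            calibrate_scale(trk, 500.0, 0.5)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_pitch_invariant_under_uniform_scaling(self, scale):
        rng = np.random.default_rng(12)
        head = np.cumsum(rng.normal(0, 1e-3, (200, 2)), axis=0) + [0.1, 0.5]
        abd = head + [0.05, -0.02]
        a = compute_pitch(_simple_track(head, abd), sg_window=31)
        b = compute_pitch(_simple_track(head * scale, abd * scale), sg_window=31)
        np.testing.assert_allclose(a.pitch_raw, b.pitch_raw, atol=1e-8)


class TestGravityCheck:
    def test_noise_free_parabola_passes(self):
        ball = simulate_ball_drop(g=9.805, noise_sd=0.0)
        g, ok = verify_gravity(ball, g_ref=9.805)
        assert ok and g == pytest.approx(9.805, rel=1e-10)

    def test_wrong_gravity_flagged(self):
        # 9.0 vs 9.805 is an 8.2% deviation, far beyond the 1% tolerance
        ball = simulate_ball_drop(g=9.0, noise_sd=0.0)
        g, ok = verify_gravity(ball, g_ref=9.805)
        assert not ok and g == pytest.approx(9.0, rel=1e-10)

    def test_noisy_drop_within_one_percent(self):
        ball = simulate_ball_drop(g=9.805, noise_sd=5e-4, duration=0.5, seed=21)
        g, ok = verify_gravity(ball, g_ref=9.805)
        assert ok and abs(g - 9.805) / 9.805 < 0.01

    def test_too_few_frames_raise(self):
        ball = simulate_ball_drop(duration=0.01)
        with pytest.raises(ValueError, match="10 frames"):
            verify_gravity(ball)


class TestPitch:
    @pytest.mark.parametrize("head,abd,expected", [
        ((1.0, 1.0), (0.0, 0.0), 45.0),
        ((0.0, -1.0), (0.0, 0.0), -90.0),   # head-first dive
        ((1.0, 0.0), (0.0, 0.0), 0.0),
    ])
    def test_raw_angle_examples(self, head, abd, expected):
        n = 80
        trk = _simple_track(np.tile(head, (n, 1)), np.tile(abd, (n, 1)))
        pp = compute_pitch(trk, sg_window=31)
        np.testing.assert_allclose(pp.pitch_raw, expected, atol=1e-10)

    def test_constant_pitch_smoother_is_identity(self):
        n = 200
        head = np.column_stack([np.linspace(0, 1, n), np.linspace(0, 0.5, n)])
        trk = _simple_track(head, head - [0.04, 0.03])
        pp = compute_pitch(trk)
        np.testing.assert_allclose(pp.pitch_smooth, pp.pitch_raw, atol=1e-9)
        np.testing.assert_allclose(pp.pitch_rate, 0.0, atol=1e-6)

    def test_coincident_landmarks_error_names_frame(self):
        head = np.ones((100, 2))
        abd = np.zeros((100, 2))
        abd[17] = head[17]
        with pytest.raises(ValueError, match="frame 17"):
            compute_pitch(_simple_track(head, abd), sg_window=31)

    def test_window_must_be_odd_and_short_enough(self):
        head = np.random.default_rng(1).normal(size=(50, 2))
        trk = _simple_track(head, head + [0.05, 0.0])
        with pytest.raises(ValueError):
            compute_pitch(trk, sg_window=30)
        with pytest.raises(ValueError):
            compute_pitch(trk, sg_window=71)

    def test_smoother_preserves_linear_ramp_everywhere(self):
        y = np.linspace(-3.0, 7.0, 400)
        assert np.max(np.abs(_savgol(y, 71, 3) - y)) < 1e-9


class TestPhases:
    def test_marks_near_generator_truth(self, default_trial):
        track, truth = default_trial
        marks = segment_phases(compute_pitch(track))
        # t1 biased a few frames early by smoothing of the asymmetric
        # pitch valley; t2 lands on the stabilization point
        assert abs(marks.t1 - truth.t1_true) <= 0.012
        assert abs(marks.t2 - truth.t2_true) <= 0.006

    def test_monotone_pitch_reports_no_recovery(self):
        t = np.arange(300) / 500.0
        pitch = -100.0 * t
        pp = PitchProfile(t=t, pitch_raw=pitch, pitch_smooth=pitch,
                          pitch_rate=np.gradient(pitch, t))
        with pytest.raises(ValueError, match="no recovery"):
            segment_phases(pp)

    def test_equal_minima_earliest_chosen(self):
        t = np.arange(500) / 500.0
        # W-shaped pitch: two equal minima at samples 100 and 300, recovery after
        pitch = np.minimum(np.abs(t - 0.2), np.abs(t - 0.6)) * 100.0
        pitch[400:] = pitch[399]
        pp = PitchProfile(t=t, pitch_raw=pitch, pitch_smooth=pitch,
                          pitch_rate=np.gradient(pitch, t))
        marks = segment_phases(pp)
        assert marks.t1 == pytest.approx(0.2, abs=2e-3)


class TestRotationalVelocity:
    def test_hand_arithmetic(self):
        # -28 deg to +44 deg over 0.18 s -> 400 deg/s
        t = np.linspace(0.0, 1.0, 501)
        pitch = np.interp(t, [0.0, 0.25, 0.43, 1.0], [-28.0, -28.0, 44.0, 44.0])
        pp = PitchProfile(t=t, pitch_raw=pitch, pitch_smooth=pitch,
                          pitch_rate=np.gradient(pitch, t))
        omega = rotational_velocity(pp, PhaseMarks(t1=0.25, t2=0.43))
        assert omega == pytest.approx(400.0, rel=1e-9)

    def test_zero_when_pitch_unchanged(self):
        t = np.linspace(0, 1, 100)
        pitch = np.full(100, 10.0)
        pp = PitchProfile(t=t, pitch_raw=pitch, pitch_smooth=pitch,
                          pitch_rate=np.zeros(100))
        assert rotational_velocity(pp, PhaseMarks(t1=0.1, t2=0.5)) == 0.0

    def test_inverted_marks_raise(self):
        t = np.linspace(0, 1, 100)
        pp = PitchProfile(t=t, pitch_raw=t, pitch_smooth=t, pitch_rate=np.ones(100))
        with pytest.raises(ValueError):
            rotational_velocity(pp, PhaseMarks(t1=0.5, t2=0.5))

    def test_recovery_within_three_percent_noise_free(self, default_trial):
        track, truth = default_trial
        pp = compute_pitch(track)
        omega = rotational_velocity(pp, segment_phases(pp))
        assert omega == pytest.approx(truth.omega_true, rel=0.03)


class TestComTrajectory:
    def test_fraction_zero_is_smoothed_head(self):
        rng = np.random.default_rng(3)
        head = np.cumsum(rng.normal(0, 1e-3, (300, 2)), axis=0)
        trk = _simple_track(head, head + [0.05, 0.0])
        com = com_trajectory(trk, com_fraction=0.0)
        np.testing.assert_allclose(com.pos[:, 0], _savgol(head[:, 0], 31, 3), atol=1e-12)

    def test_constant_velocity_zero_acceleration(self):
        n = 400
        t = np.arange(n) / 500.0
        head = np.column_stack([1.5 * t, -0.4 * t])
        trk = _simple_track(head, head + [0.05, 0.0])
        com = com_trajectory(trk)
        np.testing.assert_allclose(com.acc[20:-20], 0.0, atol=1e-9)
        np.testing.assert_allclose(com.vel[:, 0], 1.5, atol=1e-9)

    def test_ballistic_segment_recovers_gravity(self, default_trial):
        track, truth = default_trial
        com = com_trajectory(track)
        sel = (com.t > 0.05) & (com.t < truth.t1_true - 0.05)
        assert np.mean(com.acc[sel, 1]) == pytest.approx(-9.805, rel=0.01)

    def test_bad_fraction_or_window_raise(self, default_trial):
        track, _ = default_trial
        with pytest.raises(ValueError):
            com_trajectory(track, com_fraction=1.2)
        with pytest.raises(ValueError):
            com_trajectory(track, sg_window=10001)


class TestSteadyVelocities:
    def test_recovery_within_two_percent(self, default_trial):
        track, truth = default_trial
        com = com_trajectory(track)
        marks = segment_phases(compute_pitch(track))
        vx, vy, _ = steady_velocities(com, marks)
        assert vx == pytest.approx(truth.vx_steady, rel=0.02)
        assert vy == pytest.approx(truth.vy_steady, rel=0.02)

    def test_pure_ballistic_never_steady(self):
        n = 500
        t = np.arange(n) / 500.0
        head = np.column_stack([np.zeros(n), 1.5 - 0.5 * 9.805 * t**2])
        trk = _simple_track(head, head + [0.05, 0.0])
        com = com_trajectory(trk)
        with pytest.raises(ValueError, match="never met"):
            steady_velocities(com, PhaseMarks(t1=0.1, t2=0.2))

    def test_infinite_tolerance_onset_equals_t2(self, default_trial):
        track, _ = default_trial
        com = com_trajectory(track)
        marks = segment_phases(compute_pitch(track))
        _, _, out = steady_velocities(com, marks, a_tol=np.inf)
        assert out.steady_onset_vx == pytest.approx(marks.t2, abs=1e-9)
        assert out.steady_onset_vy == pytest.approx(marks.t2, abs=1e-9)

    def test_series_must_extend_beyond_t2(self, default_trial):
        track, _ = default_trial
        com = com_trajectory(track)
        with pytest.raises(ValueError):
            steady_velocities(com, PhaseMarks(t1=0.1, t2=com.t[-1]))


class TestWingbeat:
    def test_reversals_every_25_frames_give_10_hz(self):
        n = 500
        t = np.arange(n) / 500.0
        head = np.tile([0.0, 0.0], (n, 1))
        abd = np.tile([-0.05, 0.0], (n, 1))
        hinge = 0.5 * (head + abd)
        phi = np.deg2rad(60.0) * np.sin(2 * np.pi * 10.0 * t)
        wing = hinge + 0.04 * np.column_stack([np.sin(phi), np.cos(phi)])
        trk = _simple_track(head, abd, wing)
        rev = np.arange(12, n, 25)  # one full cycle per 50 frames
        freq, amp = wingbeat_stats(trk, rev, hinge_fraction=0.5)
        assert freq == pytest.approx(10.0, rel=1e-6)
        assert amp == pytest.approx(120.0, rel=0.05)

    def test_amplitude_recovered_from_generator(self, default_trial):
        track, truth = default_trial
        freq, amp = wingbeat_stats(track, track.meta["reversal_frames"],
                                   hinge_fraction=0.5, after=truth.t2_true)
        assert freq == pytest.approx(truth.wingbeat_freq, rel=0.01)
        assert amp == pytest.approx(truth.stroke_amp_true, rel=0.05)

    def test_two_reversals_insufficient(self, default_trial):
        track, _ = default_trial
        with pytest.raises(ValueError, match="3 stroke reversals"):
            wingbeat_stats(track, track.meta["reversal_frames"][:2])

    def test_no_wing_track_error(self, default_trial):
        track, _ = default_trial
        bare = track.copy()
        bare.wing = None
        with pytest.raises(ValueError, match="no wing track"):
            wingbeat_stats(bare, track.meta["reversal_frames"])


class TestLandingSpeed:
    def test_constant_velocity_magnitude(self):
        n = 400
        t = np.arange(n) / 500.0
        head = np.column_stack([1.5 * t, -0.4 * t])
        trk = _simple_track(head, head + [0.05, 0.0])
        com = com_trajectory(trk)
        v = landing_speed(com, contact_time=0.6)
        assert v == pytest.approx(np.hypot(1.5, 0.4), rel=1e-6)

    def test_warns_before_steady_onset(self):
        n = 400
        t = np.arange(n) / 500.0
        head = np.column_stack([t, np.zeros(n)])
        trk = _simple_track(head, head + [0.05, 0.0])
        com = com_trajectory(trk)
        with pytest.warns(UserWarning, match="transient"):
            v = landing_speed(com, contact_time=0.3, steady_onset=0.5)
        assert v == pytest.approx(1.0, rel=1e-6)

    def test_contact_outside_series_raises(self, default_trial):
        track, _ = default_trial
        com = com_trajectory(track)
        with pytest.raises(ValueError):
            landing_speed(com, contact_time=10.0)


class TestAnalyzeTrial:
    def test_end_to_end_recovery(self, default_trial):
        track, truth = default_trial
        s = analyze_trial(track)
        assert s.omega == pytest.approx(truth.omega_true, rel=0.03)
        assert s.mean_vx == pytest.approx(truth.vx_steady, rel=0.02)
        assert s.mean_vy == pytest.approx(truth.vy_steady, rel=0.02)
        assert s.wingbeat_freq == pytest.approx(truth.wingbeat_freq, rel=0.01)
        assert s.stroke_amp == pytest.approx(truth.stroke_amp_true, rel=0.05)
        assert s.landing_speed == pytest.approx(truth.landing_speed_true, rel=0.02)

    def test_missing_wing_yields_nan_wingbeat_only(self, default_trial):
        track, _ = default_trial
        bare = track.copy()
        bare.wing = None
        s = analyze_trial(bare)
        assert np.isnan(s.wingbeat_freq) and np.isnan(s.stroke_amp)
        assert np.isfinite(s.omega) and np.isfinite(s.mean_vx)

    def test_rerun_identical(self, noisy_trial):
        track, _ = noisy_trial
        a, b = analyze_trial(track), analyze_trial(track)
        assert a == b

    def test_uncalibrated_track_refused(self, default_trial):
        track, _ = default_trial
        px = track.copy()
        px.units_calibrated = False
        with pytest.raises(ValueError, match="calibrated"):
            analyze_trial(px)

    def test_translation_invariance(self, default_trial):
        track, _ = default_trial
        shifted = track.copy()
        shifted.head = shifted.head + [3.0, -2.0]
        shifted.abd = shifted.abd + [3.0, -2.0]
        shifted.wing = shifted.wing + [3.0, -2.0]
        a, b = analyze_trial(track), analyze_trial(shifted)
        assert a.omega == pytest.approx(b.omega, rel=1e-9)
        assert a.mean_vx == pytest.approx(b.mean_vx, rel=1e-9)
        assert a.stroke_amp == pytest.approx(b.stroke_amp, rel=1e-9)

    @pytest.mark.parametrize("angle_deg", [10.0, -25.0])
    def test_rotation_shifts_pitch_by_angle(self, default_trial, angle_deg):
        track, _ = default_trial
        th = np.deg2rad(angle_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = track.copy()
        rot.head = track.head @ R.T
        rot.abd = track.abd @ R.T
        a = compute_pitch(track)
        b = compute_pitch(rot)
        np.testing.assert_allclose(b.pitch_raw - a.pitch_raw, angle_deg, atol=1e-9)
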