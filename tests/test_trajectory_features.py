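"""Channel-peak detection, alignment, shape measures and QC."""

import numpy as np
import pytest

from myolearn import task_design as td, trajectory_features as tf
from myolearn.emg_interface import ChannelProfile, CursorTrajectory

FS = 2048


def profile_with_burst(peak_time, amplitude, width=0.2, fs=FS, duration=2.0):
    t = np.arange(int(duration * fs)) / fs
    vals = amplitude * np.clip(
        np.sin(np.pi * (t - peak_time + width / 2) / width), 0, None
    ) ** 2 * (np.abs(t - peak_time) <= width / 2)
    return ChannelProfile(vals, "hand", fs)


def brute_force_peak(values, fs, lo=0.7, hi=1.8, min_run=16):
    """Independent run-scan oracle: literal triple loop over runs."""
    best = None
    start = None
    for i in range(len(values) + 1):
        positive = i < len(values) and values[i] > 0
        if positive and start is None:
            start = i
        elif not positive and start is not None:
            if i - start > min_run:
                for j in range(start, i):
                    t = j / fs
                    if lo <= t <= hi:
                        if best is None or values[j] > best[0]:
                            best = (values[j], j, start)
            start = None
    return best


class TestChannelPeak:
    def test_single_burst_recovered(self):
        prof = profile_with_burst(1.1, 0.8)
        feats = tf.find_channel_peak(prof)
        assert feats.valid
        assert feats.peak_amplitude == pytest.approx(0.8, rel=1e-4)
        assert feats.peak_time == pytest.approx(1.1, abs=1.0 / FS)
        assert feats.initiation_time == pytest.approx(1.0, abs=2.0 / FS)

    def test_matches_brute_force_oracle(self, rng):
        vals = np.where(rng.uniform(size=6000) < 0.6,
                        rng.uniform(0, 1, 6000), 0.0)
        prof = ChannelProfile(vals, "hand", FS)
        feats = tf.find_channel_peak(prof)
        oracle = brute_force_peak(vals, FS)
        if oracle is None:
            assert not feats.valid
        else:
            assert feats.valid
            assert feats.peak_amplitude == oracle[0]
            assert feats.peak_time == oracle[1] / FS
            assert feats.initiation_time == oracle[2] / FS

    def test_all_zero_profile_invalid(self):
        feats = tf.find_channel_peak(ChannelProfile(np.zeros(4096), "hand", FS))
        assert not feats.valid

    def test_short_run_ignored(self):
        vals = np.zeros(4096)
        i = int(1.2 * FS)
        vals[i : i + 10] = 0.9  # only 10 consecutive non-zero samples
        assert not tf.find_channel_peak(ChannelProfile(vals, "hand", FS)).valid

    def test_exactly_16_samples_excluded_17_included(self):
        for run, expect in ((16, False), (17, True)):
            vals = np.zeros(4096)
            i = int(1.2 * FS)
            vals[i : i + run] = 0.5
            assert tf.find_channel_peak(
                ChannelProfile(vals, "hand", FS)).valid is expect

    def test_peak_outside_window_invalid(self):
        assert not tf.find_channel_peak(profile_with_burst(0.3, 1.0)).valid


class TestOrder:
    @pytest.mark.parametrize("congruence,direction,hand_first,expected", [
        ("congruent", "R", True, True),
        ("congruent", "L", True, False),
        ("incongruent", "R", False, True),
        ("incongruent", "L", False, False),
    ])
    def test_mapping(self, congruence, direction, hand_first, expected):
        early = tf.ChannelPeakFeatures(0.5, 0.9, 0.85, True)
        late = tf.ChannelPeakFeatures(0.5, 1.3, 1.25, True)
        hand, shin = (early, late) if hand_first else (late, early)
        assert tf.classify_order(hand, shin, direction, congruence) is expected

    def test_invalid_peaks_rejected(self):
        ok = tf.ChannelPeakFeatures(0.5, 0.9, 0.85, True)
        bad = tf.ChannelPeakFeatures.invalid()
        with pytest.raises(ValueError):
            tf.classify_order(ok, bad, "R", "congruent")


def bump_trajectory(peak_time, amplitude=200.0, width=0.5, fs=FS,
                    duration=2.0):
    t = np.arange(int(duration * fs)) / fs
    pos = amplitude * np.exp(-0.5 * ((t - peak_time) / (width / 4)) ** 2)
    return CursorTrajectory(pos, np.gradient(pos, 1 / fs), fs)


HAND = tf.ChannelPeakFeatures(0.6, 1.0, 0.95, True)
SHIN = tf.ChannelPeakFeatures(0.4, 1.45, 1.4, True)


class TestAlignment:
    def test_output_grid_and_peak_position(self):
        traj = bump_trajectory(1.3)
        aligned = tf.align_trajectory(traj, HAND, SHIN)
        assert aligned.fs == 1000
        peak_idx = np.argmax(np.abs(aligned.positions))
        assert peak_idx / 1000 == pytest.approx(1.21, abs=2e-3)

    def test_shift_invariance(self):
        a = tf.align_trajectory(bump_trajectory(1.21), HAND, SHIN)
        b = tf.align_trajectory(bump_trajectory(1.36), HAND, SHIN)
        mask = (a.times > 0.9) & (a.times < 1.5)
        np.testing.assert_allclose(
            a.positions[mask], b.positions[mask], atol=0.15
        )

    def test_identity_when_peak_already_aligned(self):
        # 1.21 s falls on the sample grid at 2000 Hz, so the shift is zero
        traj = bump_trajectory(1.21, fs=2000)
        aligned = tf.align_trajectory(traj, HAND, SHIN)
        expected = np.interp(aligned.times, traj.times, traj.positions)
        np.testing.assert_allclose(aligned.positions, expected, atol=1e-9)

    def test_idempotence(self):
        traj = bump_trajectory(1.33)
        once = tf.align_trajectory(traj, HAND, SHIN)
        as_traj = CursorTrajectory(
            np.interp(np.arange(once.positions.size * 2.048) / 2048,
                      once.times, once.positions),
            np.zeros(int(once.positions.size * 2.048)), 2048,
        )
        twice = tf.align_trajectory(as_traj, HAND, SHIN)
        mask = (once.times > 0.8) & (once.times < 1.6)
        np.testing.assert_allclose(
            twice.positions[mask], once.positions[mask],
            atol=1e-3 * np.abs(once.positions).max(),
        )


class TestShapeMeasures:
    def test_rms_zero_for_exact_path(self):
        path = td.build_path("R", 2)
        t = np.arange(2000) / 1000
        aligned = tf.AlignedTrajectory(path.displacement(t - 1.0))
        assert tf.rms_error(aligned, path) == pytest.approx(0.0, abs=1e-12)

    def test_rms_constant_offset(self):
        path = td.build_path("R", 2)
        t = np.arange(2000) / 1000
        aligned = tf.AlignedTrajectory(path.displacement(t - 1.0) + 10.0)
        assert tf.rms_error(aligned, path) == pytest.approx(10.0)

    def test_rms_matches_brute_force(self, rng):
        path = td.build_path("L", 1)
        t = np.arange(2000) / 1000
        pos = rng.uniform(-100, 100, t.size)
        aligned = tf.AlignedTrajectory(pos)
        mask = (t >= 1.0) & (t <= 1.5)
        expected = np.sqrt(np.mean(
            (pos[mask] - path.displacement(t[mask] - 1.0)) ** 2
        ))
        assert tf.rms_error(aligned, path) == pytest.approx(expected)

    def test_hits_full_and_none(self):
        path = td.build_path("R", 1)
        targets = td.make_target_points(path)
        t = np.arange(2000) / 1000
        exact = tf.AlignedTrajectory(path.displacement(t - 1.0))
        assert tf.hit_percentage(exact, targets) == 100.0
        offset = tf.AlignedTrajectory(path.displacement(t - 1.0) + 7.0)
        assert tf.hit_percentage(offset, targets) == 0.0

    def test_flat_trajectory_hits_match_geometry_oracle(self):
        path = td.build_path("R", 1)
        targets = td.make_target_points(path)
        flat = tf.AlignedTrajectory(np.zeros(2000))
        expected = 100.0 * sum(abs(p.x_px) <= 6.0 for p in targets) / 25
        assert tf.hit_percentage(flat, targets) == pytest.approx(expected)


class TestTrajectoryPeakTime:
    def test_symmetric_bump(self):
        traj = bump_trajectory(1.21)
        assert tf.trajectory_peak_time(traj, HAND, SHIN) == pytest.approx(
            1.21, abs=1.0 / FS)

    def test_search_restricted_to_interpeak_window(self):
        traj = bump_trajectory(1.2)
        spiked = traj.positions.copy()
        spiked[int(1.7 * FS)] = 10 * np.abs(traj.positions).max()
        traj2 = CursorTrajectory(spiked, traj.velocity, FS)
        assert tf.trajectory_peak_time(traj2, HAND, SHIN) == \
            tf.trajectory_peak_time(traj, HAND, SHIN)


class TestMeanProfile:
    def test_identical_profiles_average_to_themselves(self):
        prof = profile_with_burst(1.21, 0.5)
        pk = tf.find_channel_peak(prof)
        mean = tf.mean_profile([prof, prof], [pk, pk])
        # sub-sample quantisation of the detected peak allows a tiny shift
        np.testing.assert_allclose(mean, prof.values, atol=1e-3)

    def test_alignment_removes_latency_differences(self):
        a = profile_with_burst(1.1, 0.5)
        b = profile_with_burst(1.3, 0.5)
        mean = tf.mean_profile(
            [a, b], [tf.find_channel_peak(a), tf.find_channel_peak(b)]
        )
        ref = profile_with_burst(1.21, 0.5)
        core = slice(int(0.9 * FS), int(1.6 * FS))
        np.testing.assert_allclose(mean[core], ref.values[core], atol=5e-3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tf.mean_profile([], [])


class TestQC:
    @pytest.mark.parametrize("amp,pk,expected", [
        (541.0, 1.2, True),   # more than double the 270 px requirement
        (200.0, 1.6, True),   # mean peak after trial end
        (200.0, 1.2, False),
        (540.0, 1.5, False),  # boundaries are strict
    ])
    def test_exclusion_rule(self, amp, pk, expected):
        assert tf.qc_exclude(amp, pk) is expected
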