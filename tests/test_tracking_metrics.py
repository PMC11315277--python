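"""Sliding-centroid jitter metrics: oracles, invariances, boundary behavior."""

import numpy as np
import pytest

from kinectqa import (
    PeakArtifact,
    PoseSimConfig,
    compute_mde,
    cut_frames,
    distance_to_centroid,
    joint_pair_distance,
    simulate_tracking,
    sliding_centroid,
)
from kinectqa.tracking_metrics import five_number_summary

from conftest import make_sequence


def naive_mde(seq, joint, half_width, end_mode="clip"):
    """Reference MDE: recompute every window per frame with plain loops."""
    traj = seq.joint_positions(joint)
    n = traj.shape[0]
    dists = []
    for t in range(n):
        lo, hi = max(t - half_width, 0), min(t + half_width, n - 1)
        window = traj[lo : hi + 1]
        div = len(window) if end_mode == "clip" else 2 * half_width + 1
        centroid = window.sum(axis=0) / div
        dists.append(np.linalg.norm(traj[t] - centroid))
    return float(np.mean(dists)), np.array(dists)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestCutFrames:
    @pytest.mark.parametrize("length,cut,expected", [(9002, 60, 8942), (61, 60, 1)])
    def test_lengths_after_cut(self, rng, length, cut, expected):
        seq = make_sequence(rng.normal(size=(length, 3, 3)) + 1900.0)
        assert len(cut_frames(seq, cut)) == expected

    def test_zero_cut_is_identity(self, rng):
        seq = make_sequence(rng.normal(size=(10, 3, 3)) + 1900.0)
        out = cut_frames(seq, 0)
        np.testing.assert_array_equal(out.positions, seq.positions)

    def test_original_frame_indices_retained(self, rng):
        seq = make_sequence(rng.normal(size=(100, 3, 3)) + 1900.0)
        out = cut_frames(seq, 60)
        np.testing.assert_array_equal(out.frame_indices, np.arange(60, 100))

    def test_overlong_cut_rejected(self, rng):
        seq = make_sequence(rng.normal(size=(60, 3, 3)))
        with pytest.raises(ValueError):
            cut_frames(seq, 60)


class TestSlidingCentroid:
    def test_constant_trajectory_centroid_is_the_constant(self):
        seq = make_sequence(np.full((50, 3, 3), 1900.0))
        cents = sliding_centroid(seq, "PELVIS", half_width=30)
        np.testing.assert_allclose(cents.values, 1900.0)

    def test_linear_motion_interior_centroid_is_the_position(self):
        t = np.arange(100, dtype=float)
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 0] = t
        seq = make_sequence(pos, joint_names=("PELVIS",))
        cents = sliding_centroid(seq, "PELVIS", half_width=10)
        # symmetric windows: centroid x equals t on the interior
        np.testing.assert_allclose(cents.values[10:90, 0], t[10:90], atol=1e-9)

    def test_clipped_start_window_hand_value(self):
        # x(t) = t, first frame, N = 2: window {0, 1, 2}, mean = 1
        pos = np.zeros((5, 1, 3))
        pos[:, 0, 0] = np.arange(5.0)
        seq = make_sequence(pos, joint_names=("PELVIS",))
        cents = sliding_centroid(seq, "PELVIS", half_width=2, end_mode="clip")
        assert cents.values[0, 0] == pytest.approx(1.0)

    def test_full_normalization_biases_end_windows(self):
        pos = np.full((20, 1, 3), 1000.0)
        seq = make_sequence(pos, joint_names=("PELVIS",))
        clip = sliding_centroid(seq, "PELVIS", half_width=5, end_mode="clip")
        full = sliding_centroid(seq, "PELVIS", half_width=5, end_mode="full")
        assert clip.values[0, 0] == pytest.approx(1000.0)
        assert full.values[0, 0] == pytest.approx(1000.0 * 6 / 11)

    def test_unknown_joint_rejected(self, jittered_sequence):
        with pytest.raises(KeyError):
            sliding_centroid(jittered_sequence, "HEAD_TOP")


class TestDistanceToCentroid:
    def test_three_four_five(self):
        pos = np.full((30, 1, 3), 100.0)
        seq = make_sequence(pos, joint_names=("PELVIS",))
        cents = sliding_centroid(seq, "PELVIS", half_width=5)
        cents.values = cents.values - np.array([3.0, 4.0, 0.0])
        np.testing.assert_allclose(distance_to_centroid(seq, cents), 5.0)

    def test_squared_variant_squares(self):
        pos = np.full((10, 1, 3), 100.0)
        seq = make_sequence(pos, joint_names=("PELVIS",))
        cents = sliding_centroid(seq, "PELVIS", half_width=2)
        cents.values = cents.values - np.array([3.0, 4.0, 0.0])
        np.testing.assert_allclose(
            distance_to_centroid(seq, cents, squared=True), 25.0
        )

    def test_misaligned_series_rejected(self, jittered_sequence):
        cents = sliding_centroid(jittered_sequence, "PELVIS")
        shorter = cut_frames(jittered_sequence, 10)
        with pytest.raises(ValueError, match="aligned"):
            distance_to_centroid(shorter, cents)


class TestComputeMde:
    def test_constant_pose_has_zero_mde(self, static_pose):
        cfg = PoseSimConfig(true_positions=static_pose, sigma_mm=0.0, n_frames=120, seed=0)
        seq = simulate_tracking(cfg)
        result = compute_mde(seq)
        assert all(v == 0.0 for v in result.mde.values())
        assert result.median == 0.0

    def test_matches_naive_reference_exactly(self, jittered_sequence):
        seq = cut_frames(jittered_sequence, 60)
        result = compute_mde(seq, joints=["PELVIS", "ANKLE_LEFT"], half_width=30)
        for joint in ("PELVIS", "ANKLE_LEFT"):
            ref_mde, ref_series = naive_mde(seq, joint, 30)
            # cumulative-sum accumulation differs from the looped sum at
            # the last few bits only
            np.testing.assert_allclose(result.series[joint], ref_series, rtol=1e-9)
            assert result.mde[joint] == pytest.approx(ref_mde, rel=1e-10)

    def test_linear_motion_error_only_at_clipped_ends(self):
        pos = np.zeros((200, 1, 3))
        pos[:, 0, 0] = np.arange(200.0)
        seq = make_sequence(pos, joint_names=("PELVIS",))
        result = compute_mde(seq, joints=["PELVIS"], half_width=20)
        series = result.series["PELVIS"]
        np.testing.assert_allclose(series[20:180], 0.0, atol=1e-9)
        assert series[0] > 0 and series[-1] > 0
        assert result.mde["PELVIS"] > 0

    def test_translation_invariance_is_exact(self, jittered_sequence):
        seq = cut_frames(jittered_sequence, 60)
        shifted = seq.replace_positions(seq.positions + np.array([123.0, -456.0, 789.0]))
        a = compute_mde(seq, half_width=15)
        b = compute_mde(shifted, half_width=15)
        for joint in a.mde:
            assert b.mde[joint] == pytest.approx(a.mde[joint], rel=1e-9)

    def test_rotation_invariance(self, jittered_sequence, rng):
        seq = cut_frames(jittered_sequence, 60)
        rot = random_rotation(rng)
        rotated = seq.replace_positions(seq.positions @ rot.T)
        a = compute_mde(seq, half_width=15)
        b = compute_mde(rotated, half_width=15)
        for joint in a.mde:
            assert b.mde[joint] == pytest.approx(a.mde[joint], rel=1e-9)

    def test_peak_injection_raises_only_that_joints_mde(self, static_pose):
        base_cfg = PoseSimConfig(
            true_positions=static_pose, sigma_mm=1.0, n_frames=500, seed=31
        )
        peak_cfg = PoseSimConfig(
            true_positions=static_pose, sigma_mm=1.0, n_frames=500, seed=31,
            peak=PeakArtifact("ANKLE_LEFT", 250, 40, (0.0, 20.0, 0.0)),
        )
        a = compute_mde(simulate_tracking(base_cfg))
        b = compute_mde(simulate_tracking(peak_cfg))
        assert b.mde["ANKLE_LEFT"] > a.mde["ANKLE_LEFT"]
        for joint in a.mde:
            if joint != "ANKLE_LEFT":
                assert b.mde[joint] == a.mde[joint]

    def test_empty_joint_selection_rejected(self, jittered_sequence):
        with pytest.raises(ValueError):
            compute_mde(jittered_sequence, joints=[])


class TestJointPairDistance:
    def test_noiseless_ankles_give_constant_stance_width(self):
        pos = np.zeros((40, 3, 3))
        pos[:, 1, 0] = 50.0  # ANKLE_LEFT
        pos[:, 2, 0] = -50.0  # ANKLE_RIGHT
        seq = make_sequence(pos)
        series = joint_pair_distance(seq, "ANKLE_LEFT", "ANKLE_RIGHT")
        np.testing.assert_allclose(series.distances, 100.0)
        assert series.summary.min == series.summary.max == 100.0

    def test_symmetric_in_the_pair(self, jittered_sequence):
        ab = joint_pair_distance(jittered_sequence, "ANKLE_LEFT", "ANKLE_RIGHT")
        ba = joint_pair_distance(jittered_sequence, "ANKLE_RIGHT", "ANKLE_LEFT")
        np.testing.assert_array_equal(ab.distances, ba.distances)

    def test_identical_joints_rejected(self, jittered_sequence):
        with pytest.raises(ValueError):
            joint_pair_distance(jittered_sequence, "ANKLE_LEFT", "ANKLE_LEFT")

    def test_jitter_inflates_mean_distance(self, static_pose):
        # E||a - b|| >= ||E(a - b)|| (Jensen); noticeable at sigma ~ separation
        pose = {"ANKLE_LEFT": (50.0, 0.0, 1900.0), "ANKLE_RIGHT": (-50.0, 0.0, 1900.0)}
        cfg = PoseSimConfig(true_positions=pose, sigma_mm=40.0, n_frames=4000, seed=77)
        seq = simulate_tracking(cfg)
        series = joint_pair_distance(seq, "ANKLE_LEFT", "ANKLE_RIGHT")
        assert series.distances.mean() > 100.0

    def test_rotation_invariance_of_pair_distance(self, jittered_sequence, rng):
        rot = random_rotation(rng)
        rotated = jittered_sequence.replace_positions(jittered_sequence.positions @ rot.T)
        a = joint_pair_distance(jittered_sequence, "ANKLE_LEFT", "ANKLE_RIGHT")
        b = joint_pair_distance(rotated, "ANKLE_LEFT", "ANKLE_RIGHT")
        np.testing.assert_allclose(a.distances, b.distances, rtol=1e-9)


class TestFiveNumberSummary:
    def test_ordering_invariant(self, rng):
        s = five_number_summary(rng.normal(size=500))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            five_number_summary(np.array([]))
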