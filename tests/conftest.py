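import json

import numpy as np
import pytest

from kinectqa import (
    DepthFrameStack,
    PoseSimConfig,
    TrackingSequence,
    default_static_pose,
    simulate_tracking,
)
from kinectqa.joints import JOINT_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(20240809)


@pytest.fixture
def static_pose():
    return default_static_pose()


def make_sequence(positions, joint_names=("PELVIS", "ANKLE_LEFT", "ANKLE_RIGHT"), fps=30.0):
    """TrackingSequence from an (n, n_joints, 3) array."""
    positions = np.asarray(positions, dtype=np.float64)
    return TrackingSequence(
        positions=positions,
        joint_names=tuple(joint_names),
        frame_indices=np.arange(positions.shape[0]),
        fps=fps,
    )


def make_tracking_file(tmp_path, frames, joint_names=None, name="tracking.json"):
    """Write a body-tracking JSON file from a list of frame dicts."""
    doc = {"frames": frames, "fps": 30}
    if joint_names is not None:
        doc["joint_names"] = list(joint_names)
    path = tmp_path / name
    path.write_text(json.dumps(doc))
    return path


def body_frame(frame_id, positions, n_bodies=1, timestamp=None):
    entry = {"frame_id": frame_id, "num_bodies": n_bodies, "bodies": []}
    if timestamp is not None:
        entry["timestamp_usec"] = timestamp
    for b in range(n_bodies):
        entry["bodies"].append(
            {"body_id": b, "joint_positions": np.asarray(positions).tolist()}
        )
    return entry


def constant_positions_32(value=(0.0, 0.0, 1900.0)):
    return np.tile(np.asarray(value, dtype=float), (len(JOINT_NAMES), 1))


@pytest.fixture
def jittered_sequence(static_pose):
    """A short study-style sequence: static pose + 1 mm jitter, no transient."""
    cfg = PoseSimConfig(
        true_positions=static_pose, sigma_mm=1.0, n_frames=400, seed=42
    )
    return simulate_tracking(cfg)


def make_stack(frames, fps=30.0):
    return DepthFrameStack(frames=np.asarray(frames), fps=fps)
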