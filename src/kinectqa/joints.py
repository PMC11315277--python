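"""Joint-name vocabulary of the Azure Kinect Body Tracking SDK.

The SDK reports 32 named joints per body in a fixed index order
(``k4abt_joint_id_t``).  Names are case-sensitive and the set is closed:
anything outside :data:`JOINT_NAMES` is rejected at the API boundary.
"""

from __future__ import annotations

#: The 32 joints in SDK index order.  Files that omit an explicit
#: joint-name list are interpreted against this order.
JOINT_NAMES: tuple[str, ...] = (
    "PELVIS",
    "SPINE_NAVEL",
    "SPINE_CHEST",
    "NECK",
    "CLAVICLE_LEFT",
    "SHOULDER_LEFT",
    "ELBOW_LEFT",
    "WRIST_LEFT",
    "HAND_LEFT",
    "HANDTIP_LEFT",
    "THUMB_LEFT",
    "CLAVICLE_RIGHT",
    "SHOULDER_RIGHT",
    "ELBOW_RIGHT",
    "WRIST_RIGHT",
    "HAND_RIGHT",
    "HANDTIP_RIGHT",
    "THUMB_RIGHT",
    "HIP_LEFT",
    "KNEE_LEFT",
    "ANKLE_LEFT",
    "FOOT_LEFT",
    "HIP_RIGHT",
    "KNEE_RIGHT",
    "ANKLE_RIGHT",
    "FOOT_RIGHT",
    "HEAD",
    "NOSE",
    "EYE_LEFT",
    "EAR_LEFT",
    "EYE_RIGHT",
    "EAR_RIGHT",
)

#: The 18 joints most relevant for gait and posture analysis (trunk, arms
#: without hands, legs).  This is the default joint selection for MDE
#: summaries.
ANALYSIS_JOINTS: tuple[str, ...] = (
    "PELVIS",
    "SPINE_NAVEL",
    "SPINE_CHEST",
    "NECK",
    "SHOULDER_LEFT",
    "ELBOW_LEFT",
    "WRIST_LEFT",
    "SHOULDER_RIGHT",
    "ELBOW_RIGHT",
    "WRIST_RIGHT",
    "HIP_LEFT",
    "KNEE_LEFT",
    "ANKLE_LEFT",
    "FOOT_LEFT",
    "HIP_RIGHT",
    "KNEE_RIGHT",
    "ANKLE_RIGHT",
    "FOOT_RIGHT",
)

_JOINT_SET = frozenset(JOINT_NAMES)


def validate_joint(name: str) -> str:
    """Return *name* if it is one of the 32 SDK joints, else raise KeyError."""
    if name not in _JOINT_SET:
        raise KeyError(f"unknown joint name: {name!r}")
    return name
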