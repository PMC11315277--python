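"""Readers and writers for body-tracking JSON, depth-frame stacks and
condition metadata, plus the in-memory containers shared by all metrics.

Conventions
-----------
* All positions and depths are **millimetres** in camera space: x points
  right of the focal point, y points down, z points forward.
* Frame indices are 0-based internally.  "Drop the first 60 frames"
  therefore means dropping indices 0–59.
* Depth stacks are carried as sequences of 16-bit single-channel PNG
  files plus a JSON manifest; the invalid-measurement sentinel is
  normalized to 0 on read.

Body-tracking JSON dialect (the ``offline_processor`` sample of the
Azure Kinect SDK)::

    {
      "joint_names": ["PELVIS", ...],        # optional; SDK order assumed if absent
      "fps": 30,                             # optional, default 30
      "frames": [
        {
          "frame_id": 0,
          "timestamp_usec": 33333,           # optional
          "num_bodies": 1,
          "bodies": [
            {"body_id": 0,
             "joint_positions": [[x, y, z], ... one triple per joint],
             "joint_orientations": [...]}    # optional, passed through on read only
          ]
        },
        ...
      ]
    }

Frames with zero bodies are legal: they are recorded as gaps (excluded
from the stored trajectory and listed in ``TrackingSequence.gap_frames``).
When several bodies appear in one frame, body 0 is taken and a warning is
logged; the recordings this package targets contain a single subject.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .joints import JOINT_NAMES, validate_joint

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "TrackingFormatError",
    "DepthFormatError",
    "RegionOfInterest",
    "ConditionMetadata",
    "TrackingSequence",
    "DepthFrameStack",
    "read_tracking_json",
    "write_tracking_json",
    "read_depth_stack",
    "write_depth_stack",
    "read_condition_metadata",
    "write_condition_metadata",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class TrackingFormatError(FormatError):
    pass


class DepthFormatError(FormatError):
    pass


@dataclass(frozen=True)
class RegionOfInterest:
    """A rectangular pixel region, 0-based, top-left origin."""

    name: str
    row_start: int
    col_start: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must have positive size")

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_start + self.height),
            slice(self.col_start, self.col_start + self.width),
        )

    def check_inside(self, frame_height: int, frame_width: int) -> None:
        if (
            self.row_start + self.height > frame_height
            or self.col_start + self.width > frame_width
        ):
            raise ValueError(
                f"ROI {self.name!r} ({self.row_start},{self.col_start})+"
                f"{self.height}x{self.width} exceeds frame "
                f"{frame_height}x{frame_width}"
            )


@dataclass(frozen=True)
class ConditionMetadata:
    """Lighting condition of one recording (ambient + infrared)."""

    label: str
    ceiling_light: bool = False
    infrared_lamp: bool = False
    blinds_up: bool = False
    mean_illuminance_lux: float = 0.0
    mean_infrared_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_illuminance_lux < 0:
            raise ValueError("illuminance must be >= 0")
        if self.mean_infrared_intensity < 0:
            raise ValueError("infrared intensity must be >= 0")


@dataclass
class TrackingSequence:
    """Per-frame 3D joint positions for one tracked body.

    ``positions`` has shape (n_frames, n_joints, 3) in mm; rows align with
    ``frame_indices`` (strictly increasing original frame numbers).  Frames
    in which no body was detected are not stored; their indices are kept in
    ``gap_frames``.
    """

    positions: np.ndarray
    joint_names: tuple[str, ...]
    frame_indices: np.ndarray
    fps: float = 30.0
    timestamps_usec: np.ndarray | None = None
    gap_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_joints, 3)")
        if self.positions.shape[0] != self.frame_indices.shape[0]:
            raise ValueError("positions and frame_indices disagree on length")
        if self.positions.shape[1] != len(self.joint_names):
            raise ValueError("positions and joint_names disagree on joint count")
        if len(self.joint_names) == 0:
            raise ValueError("joint set must not be empty")
        for name in self.joint_names:
            validate_joint(name)
        if len(set(self.joint_names)) != len(self.joint_names):
            raise ValueError("duplicate joint names")
        if self.frame_indices.size and np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame_indices must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not in this sequence") from None

    def joint_positions(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one joint, mm."""
        return self.positions[:, self.joint_index(name), :]

    def replace_positions(self, positions: np.ndarray) -> "TrackingSequence":
        return TrackingSequence(
            positions=positions,
            joint_names=self.joint_names,
            frame_indices=self.frame_indices.copy(),
            fps=self.fps,
            timestamps_usec=None
            if self.timestamps_usec is None
            else self.timestamps_usec.copy(),
            gap_frames=self.gap_frames,
        )


@dataclass
class DepthFrameStack:
    """T×H×W stack of depth values in mm; 0 marks an invalid measurement."""

    frames: np.ndarray
    fps: float = 30.0
    invalid_sentinel: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (T, H, W)")
        if np.any(self.frames < 0):
            raise ValueError("depth values must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def valid_mask(self) -> np.ndarray:
        """Boolean T×H×W mask; True where a usable depth value exists."""
        return self.frames != self.invalid_sentinel


# ---------------------------------------------------------------------------
# body-tracking JSON


def _parse_body_frame(
    entry: dict, i: int, n_joints: int
) -> tuple[int, int | None, np.ndarray | None]:
    if not isinstance(entry, dict):
        raise TrackingFormatError(f"frame {i}: expected an object")
    frame_id = int(entry.get("frame_id", i))
    ts = entry.get("timestamp_usec")
    bodies = entry.get("bodies", [])
    if not isinstance(bodies, list):
        raise TrackingFormatError(f"frame {i}: 'bodies' must be a list")
    if len(bodies) == 0:
        return frame_id, ts, None
    if len(bodies) > 1:
        logger.warning(
            "frame %d holds %d bodies; taking body 0", frame_id, len(bodies)
        )
    joints = bodies[0].get("joint_positions")
    if joints is None:
        raise TrackingFormatError(f"frame {i}: body without 'joint_positions'")
    pos = np.asarray(joints, dtype=np.float64)
    if pos.shape != (n_joints, 3):
        raise TrackingFormatError(
            f"frame {i}: expected {n_joints} joint position triples, "
            f"got shape {pos.shape}"
        )
    return frame_id, ts, pos


def read_tracking_json(path: str | os.PathLike) -> TrackingSequence:
    """Read a body-tracking JSON file into a :class:`TrackingSequence`.

    The first body of each frame is kept; bodiless frames become gaps.
    Files without a ``joint_names`` list must carry exactly 32 joints in
    SDK order; with an explicit list any closed subset of the 32 names is
    accepted (permissive mode).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise TrackingFormatError(f"{path}: empty file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TrackingFormatError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise TrackingFormatError(f"{path}: missing top-level 'frames' list")
    raw_names = doc.get("joint_names")
    if raw_names is None:
        joint_names = JOINT_NAMES
    else:
        joint_names = tuple(validate_joint(n) for n in raw_names)
    n_joints = len(joint_names)
    if raw_names is None and n_joints != 32:  # defensive; JOINT_NAMES has 32
        raise TrackingFormatError(f"{path}: implicit joint order requires 32 joints")

    frame_ids: list[int] = []
    stamps: list[int] = []
    rows: list[np.ndarray] = []
    gaps: list[int] = []
    have_all_stamps = True
    for i, entry in enumerate(doc["frames"]):
        try:
            frame_id, ts, pos = _parse_body_frame(entry, i, n_joints)
        except TrackingFormatError:
            raise
        except (TypeError, ValueError, KeyError, AttributeError) as exc:
            raise TrackingFormatError(f"{path}: frame {i}: {exc}") from exc
        if pos is None:
            gaps.append(frame_id)
            continue
        frame_ids.append(frame_id)
        if ts is None:
            have_all_stamps = False
        else:
            stamps.append(int(ts))
        rows.append(pos)
    if not rows:
        raise TrackingFormatError(f"{path}: no frames with a tracked body")
    if gaps:
        logger.info("%s: %d bodiless frames recorded as gaps", path, len(gaps))
    return TrackingSequence(
        positions=np.stack(rows),
        joint_names=joint_names,
        frame_indices=np.asarray(frame_ids),
        fps=float(doc.get("fps", 30.0)),
        timestamps_usec=np.asarray(stamps) if have_all_stamps and stamps else None,
        gap_frames=tuple(gaps),
    )


def write_tracking_json(seq: TrackingSequence, path: str | os.PathLike) -> None:
    """Write *seq* in the dialect :func:`read_tracking_json` accepts.

    Gap frames are written back as bodiless frames so that a round trip
    preserves the full frame structure.
    """
    if len(seq.joint_names) == 0:
        raise ValueError("cannot write a sequence with an empty joint set")
    frames: list[dict] = []
    gap_set = set(seq.gap_frames)
    by_id = {int(fid): row for row, fid in enumerate(seq.frame_indices)}
    all_ids = sorted(set(map(int, seq.frame_indices)) | gap_set)
    for fid in all_ids:
        entry: dict = {"frame_id": fid}
        if fid in gap_set and fid not in by_id:
            entry["num_bodies"] = 0
            entry["bodies"] = []
        else:
            row = by_id[fid]
            if seq.timestamps_usec is not None:
                entry["timestamp_usec"] = int(seq.timestamps_usec[row])
            entry["num_bodies"] = 1
            entry["bodies"] = [
                {
                    "body_id": 0,
                    "joint_positions": seq.positions[row].tolist(),
                }
            ]
        frames.append(entry)
    doc = {
        "joint_names": list(seq.joint_names),
        "fps": seq.fps,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# depth stacks: 16-bit grayscale PNG files + manifest.json


def read_depth_stack(manifest_path: str | os.PathLike) -> DepthFrameStack:
    """Load a depth stack from a JSON manifest naming ordered 16-bit PNGs.

    Values equal to the manifest's ``invalid_sentinel`` are normalized to
    0, the in-memory sentinel.
    """
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise DepthFormatError(f"{manifest_path}: malformed JSON: {exc}") from exc
    for key in ("width", "height", "frames"):
        if key not in manifest:
            raise DepthFormatError(f"{manifest_path}: manifest missing {key!r}")
    width = int(manifest["width"])
    height = int(manifest["height"])
    sentinel = int(manifest.get("invalid_sentinel", 0))
    fps = float(manifest.get("fps", 30.0))
    base = manifest_path.parent
    frames = np.empty((len(manifest["frames"]), height, width), dtype=np.uint16)
    for t, rel in enumerate(manifest["frames"]):
        img = iio.imread(base / rel)
        if img.dtype != np.uint16:
            raise DepthFormatError(
                f"{rel}: expected 16-bit single-channel image, got dtype {img.dtype}"
            )
        if img.ndim != 2 or img.shape != (height, width):
            raise DepthFormatError(
                f"{rel}: expected {height}x{width} single-channel image, "
                f"got shape {img.shape}"
            )
        frames[t] = img
    if sentinel != 0:
        frames = np.where(frames == sentinel, 0, frames)
    return DepthFrameStack(frames=frames, fps=fps, invalid_sentinel=0)


def write_depth_stack(
    stack: DepthFrameStack, out_dir: str | os.PathLike, prefix: str = "depth"
) -> Path:
    """Write a stack as 16-bit PNGs plus ``manifest.json``; returns the manifest path."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if np.any(stack.frames > np.iinfo(np.uint16).max):
        raise ValueError("depth values exceed the 16-bit range")
    names = []
    digits = max(5, len(str(stack.n_frames)))
    for t in range(stack.n_frames):
        name = f"{prefix}_{t:0{digits}d}.png"
        iio.imwrite(out_dir / name, stack.frames[t].astype(np.uint16))
        names.append(name)
    manifest = {
        "width": stack.width,
        "height": stack.height,
        "fps": stack.fps,
        "invalid_sentinel": int(stack.invalid_sentinel),
        "frames": names,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


# ---------------------------------------------------------------------------
# condition metadata sidecar


def read_condition_metadata(path: str | os.PathLike) -> ConditionMetadata:
    doc = json.loads(Path(path).read_text())
    return ConditionMetadata(
        label=doc["label"],
        ceiling_light=bool(doc.get("ceiling_light", False)),
        infrared_lamp=bool(doc.get("infrared_lamp", False)),
        blinds_up=bool(doc.get("blinds_up", False)),
        mean_illuminance_lux=float(doc.get("mean_illuminance_lux", 0.0)),
        mean_infrared_intensity=float(doc.get("mean_infrared_intensity", 0.0)),
    )


def write_condition_metadata(meta: ConditionMetadata, path: str | os.PathLike) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "label": meta.label,
                "ceiling_light": meta.ceiling_light,
                "infrared_lamp": meta.infrared_lamp,
                "blinds_up": meta.blinds_up,
                "mean_illuminance_lux": meta.mean_illuminance_lux,
                "mean_infrared_intensity": meta.mean_infrared_intensity,
            },
            indent=1,
        )
    )
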