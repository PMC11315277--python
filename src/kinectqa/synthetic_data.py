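"""Synthetic depth stacks and body-tracking sequences with known ground truth.

The generator emulates the statistical structure the downstream metrics
assume for a static scene recorded by a time-of-flight depth camera with
markerless body tracking:

* depth stacks: per-pixel Gaussian noise at the 1–3 mm scale, rounded to
  integer mm, per-pixel invalid-measurement probability (elevated in a
  boundary band between object and background, where mixed fore/background
  signal produces dropouts), and an optional moving circular drop-out blob
  (a dust-particle-style artifact crossing the image);
* tracking sequences: a static true pose plus per-joint isotropic Gaussian
  jitter, an exponentially decaying convergence transient over the first
  ~60 frames (the tracker settling on the pose), and an optional transient
  position "peak" on one joint.

Noise is independent across frames by default, because the study-style
summary statistics only constrain marginal dispersions; an optional AR(1)
coefficient adds temporal correlation for sensitivity analyses.

Defaults reproduce the study conditions of a mannequin ~1.9 m in front of
the camera: 30 fps, 9002-frame (5-minute) recordings, per-joint jitter at
the mm scale observed for such recordings, and per-condition jitter scale
factors for four lighting conditions (ambient ceiling light and an
additional infrared lamp, each on/off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import DepthFrameStack, TrackingSequence
from .joints import JOINT_NAMES, validate_joint

__all__ = [
    "BlobArtifact",
    "DepthSimConfig",
    "TransientConfig",
    "PeakArtifact",
    "PoseSimConfig",
    "simulate_depth",
    "simulate_tracking",
    "default_static_pose",
    "default_joint_jitter_mm",
    "condition_jitter_scales",
    "roi_depth_sim_config",
    "CHI3_MEAN_RATIO",
]

#: E|N3(0, I)| = sqrt(8/pi): mean length of an isotropic 3D Gaussian with
#: unit per-axis SD.  Converts a jitter SD into the expected
#: distance-to-centroid (up to the finite-window factor sqrt(2N/(2N+1))).
CHI3_MEAN_RATIO: float = float(np.sqrt(8.0 / np.pi))

#: Mean distance error (mm) per joint for a static mannequin under the
#: baseline lighting condition (ambient and infrared lamps both off);
#: jitter SDs are derived from these via the chi-3 factor.
_BASELINE_MDE_MM: dict[str, float] = {
    "PELVIS": 0.62,
    "SPINE_NAVEL": 0.68,
    "SPINE_CHEST": 0.87,
    "NECK": 1.11,
    "SHOULDER_LEFT": 1.21,
    "ELBOW_LEFT": 1.34,
    "WRIST_LEFT": 2.57,
    "SHOULDER_RIGHT": 1.08,
    "ELBOW_RIGHT": 0.92,
    "WRIST_RIGHT": 0.99,
    "HIP_LEFT": 0.74,
    "KNEE_LEFT": 0.90,
    "ANKLE_LEFT": 1.67,
    "FOOT_LEFT": 2.46,
    "HIP_RIGHT": 0.74,
    "KNEE_RIGHT": 0.83,
    "ANKLE_RIGHT": 1.76,
    "FOOT_RIGHT": 3.31,
}

# finite-window correction for N = 30: sqrt(2N/(2N+1))
_WINDOW_FACTOR_N30 = float(np.sqrt(60.0 / 61.0))


def default_joint_jitter_mm() -> dict[str, float]:
    """Per-joint isotropic jitter SD (mm) for the baseline condition.

    Derived by inverting the chi-3 expectation MDE = σ·sqrt(8/π)·sqrt(2N/(2N+1))
    at N = 30 from baseline per-joint MDE values; joints outside the
    18-joint analysis set get the median jitter.
    """
    factor = CHI3_MEAN_RATIO * _WINDOW_FACTOR_N30
    sigma = {j: mde / factor for j, mde in _BASELINE_MDE_MM.items()}
    med = float(np.median(list(sigma.values())))
    for j in JOINT_NAMES:
        sigma.setdefault(j, med)
    return sigma


def condition_jitter_scales() -> dict[str, float]:
    """Jitter scale factors for the four lighting conditions.

    Ratios of the median per-joint MDE of each condition to the baseline
    median (1.03 mm): additional infrared light raises tracking jitter,
    ambient light alone barely does.
    """
    return {
        "LightOff_IrOff": 1.00,
        "LightOff_IrOn": 1.19,
        "LightOn_IrOff": 1.07,
        "LightOn_IrOn": 1.34,
    }


# ---------------------------------------------------------------------------
# depth simulation


@dataclass(frozen=True)
class BlobArtifact:
    """A moving circular drop-out: pixels under the disk become invalid."""

    start_frame: int
    end_frame: int
    radius: float
    velocity: tuple[float, float]  # (rows, cols) per frame
    start: tuple[float, float]  # (row, col) at start_frame

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("blob end_frame before start_frame")
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")

    def mask(self, t: int, height: int, width: int) -> np.ndarray | None:
        """Boolean H×W disk mask at frame *t*, or None outside the window."""
        if not (self.start_frame <= t <= self.end_frame):
            return None
        dt = t - self.start_frame
        r0 = self.start[0] + self.velocity[0] * dt
        c0 = self.start[1] + self.velocity[1] * dt
        rows = np.arange(height)[:, None] - r0
        cols = np.arange(width)[None, :] - c0
        return rows * rows + cols * cols <= self.radius * self.radius


@dataclass
class DepthSimConfig:
    """Scene + noise model for a synthetic depth recording.

    ``base_depth_map`` is the noiseless scene (mm); ``sigma_map`` the
    per-pixel noise SD (mm); ``invalid_prob_map`` the per-frame probability
    of a pixel dropping out.
    """

    base_depth_map: np.ndarray
    sigma_map: np.ndarray
    invalid_prob_map: np.ndarray
    n_frames: int = 9002
    fps: float = 30.0
    seed: int = 0
    blob: BlobArtifact | None = None

    def __post_init__(self) -> None:
        self.base_depth_map = np.asarray(self.base_depth_map, dtype=np.float64)
        shape = self.base_depth_map.shape
        self.sigma_map = np.broadcast_to(
            np.asarray(self.sigma_map, dtype=np.float64), shape
        ).copy()
        self.invalid_prob_map = np.broadcast_to(
            np.asarray(self.invalid_prob_map, dtype=np.float64), shape
        ).copy()
        if self.base_depth_map.ndim != 2:
            raise ValueError("base_depth_map must be 2-D")
        if np.any(self.sigma_map < 0):
            raise ValueError("sigma_map must be >= 0")
        if np.any((self.invalid_prob_map < 0) | (self.invalid_prob_map > 1)):
            raise ValueError("invalid_prob_map must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def simulate_depth(cfg: DepthSimConfig) -> DepthFrameStack:
    """Draw a depth stack: rounded Gaussian noise, dropouts, optional blob.

    Per frame and pixel the value is ``round(base + ε)`` with
    ``ε ~ N(0, sigma²)``; with the configured probability the pixel is set
    to the invalid sentinel (0) instead.  Values simulated below zero are
    clamped to invalid and counted in ``stack.notes["n_negative_clamped"]``.
    Identical config + seed give a bit-identical stack.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    h, w = cfg.base_depth_map.shape
    frames = np.empty((cfg.n_frames, h, w), dtype=np.uint16)
    n_negative = 0
    any_sigma = bool(np.any(cfg.sigma_map > 0))
    any_invalid = bool(np.any(cfg.invalid_prob_map > 0))
    for t in range(cfg.n_frames):
        if any_sigma:
            vals = cfg.base_depth_map + rng.normal(0.0, 1.0, size=(h, w)) * cfg.sigma_map
        else:
            vals = cfg.base_depth_map.copy()
        vals = np.rint(vals)
        neg = vals < 0
        n_negative += int(neg.sum())
        vals[neg] = 0
        if any_invalid:
            drop = rng.random((h, w)) < cfg.invalid_prob_map
            vals[drop] = 0
        if cfg.blob is not None:
            m = cfg.blob.mask(t, h, w)
            if m is not None:
                vals[m] = 0
        frames[t] = vals.astype(np.uint16)
    return DepthFrameStack(
        frames=frames,
        fps=cfg.fps,
        invalid_sentinel=0,
        notes={"n_negative_clamped": n_negative, "seed": cfg.seed},
    )


def roi_depth_sim_config(
    size: int,
    base_depth_mm: float = 1900.0,
    sigma_mm: float = 1.2,
    boundary_band: int = 0,
    boundary_sigma_mm: float = 3.5,
    boundary_invalid_prob: float = 0.08,
    n_frames: int = 9002,
    seed: int = 0,
) -> DepthSimConfig:
    """Study-style ROI scene: flat object patch, optional noisy boundary band.

    With ``boundary_band > 0`` the last columns model the object/background
    boundary: background depth (object + 500 mm), inflated noise and an
    elevated dropout probability — the mixed-signal band where real
    recordings concentrate their invalid values.  Without a band the whole
    patch is object surface with uniform noise and no dropouts.
    """
    base = np.full((size, size), base_depth_mm)
    sigma = np.full((size, size), sigma_mm)
    prob = np.zeros((size, size))
    if boundary_band > 0:
        base[:, -boundary_band:] = base_depth_mm + 500.0
        sigma[:, -boundary_band:] = boundary_sigma_mm
        prob[:, -boundary_band:] = boundary_invalid_prob
    return DepthSimConfig(
        base_depth_map=base,
        sigma_map=sigma,
        invalid_prob_map=prob,
        n_frames=n_frames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tracking simulation


@dataclass(frozen=True)
class TransientConfig:
    """Converging start-up transient: offset·decay^t added to every joint.

    ``decay`` defaults to the value that shrinks the offset below 1% of its
    initial size within ``length`` frames (0.01^(1/length)).
    """

    length: int = 60
    offset_mm: tuple[float, float, float] = (0.0, 30.0, 15.0)
    decay: float | None = None

    def rate(self) -> float:
        if self.decay is not None:
            return self.decay
        return 0.01 ** (1.0 / max(self.length, 1))


@dataclass(frozen=True)
class PeakArtifact:
    """A transient position excursion on one joint (drop-out-blob aftermath)."""

    joint: str
    start_frame: int
    duration: int
    offset_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        validate_joint(self.joint)
        if self.duration < 1:
            raise ValueError("peak duration must be >= 1")


@dataclass
class PoseSimConfig:
    """Static pose + jitter model for a synthetic tracking recording."""

    true_positions: Mapping[str, tuple[float, float, float]]
    sigma_mm: Mapping[str, float] | float = 1.0
    n_frames: int = 9002
    fps: float = 30.0
    seed: int = 0
    transient: TransientConfig | None = None
    peak: PeakArtifact | None = None
    ar1_rho: float = 0.0

    def __post_init__(self) -> None:
        for j in self.true_positions:
            validate_joint(j)
        if isinstance(self.sigma_mm, Mapping):
            for j, s in self.sigma_mm.items():
                validate_joint(j)
                if j not in self.true_positions:
                    raise ValueError(f"sigma given for joint {j!r} without a true position")
                if s < 0:
                    raise ValueError("sigma must be >= 0")
        elif self.sigma_mm < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.peak is not None and self.peak.joint not in self.true_positions:
            raise ValueError(f"peak joint {self.peak.joint!r} has no true position")


def simulate_tracking(cfg: PoseSimConfig) -> TrackingSequence:
    """Draw a tracking sequence around a static pose.

    position[j, t] = true[j] + transient(t) + peak(j, t) + η with
    η ~ N(0, σ_j² I₃), independent across joints and (by default) frames.
    The noise stream is drawn before artifacts are added, so toggling the
    peak or transient does not change any joint's noise realization.
    """
    joint_names = tuple(cfg.true_positions.keys())
    n_joints = len(joint_names)
    if isinstance(cfg.sigma_mm, Mapping):
        sigma = np.array([float(cfg.sigma_mm.get(j, 0.0)) for j in joint_names])
    else:
        sigma = np.full(n_joints, float(cfg.sigma_mm))
    true = np.array([cfg.true_positions[j] for j in joint_names], dtype=np.float64)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    noise = rng.normal(0.0, 1.0, size=(cfg.n_frames, n_joints, 3))
    if cfg.ar1_rho != 0.0:
        # AR(1) filter preserving the marginal SD
        rho = cfg.ar1_rho
        scale = np.sqrt(1.0 - rho * rho)
        from scipy.signal import lfilter

        noise = lfilter([scale], [1.0, -rho], noise, axis=0)
        noise[0] /= scale  # first frame keeps unit variance
    positions = true[None, :, :] + noise * sigma[None, :, None]

    if cfg.transient is not None:
        rate = cfg.transient.rate()
        decay = rate ** np.arange(cfg.n_frames, dtype=np.float64)
        offset = np.asarray(cfg.transient.offset_mm, dtype=np.float64)
        positions += decay[:, None, None] * offset[None, None, :]

    if cfg.peak is not None:
        j = joint_names.index(cfg.peak.joint)
        t0 = cfg.peak.start_frame
        t1 = min(t0 + cfg.peak.duration, cfg.n_frames)
        positions[t0:t1, j, :] += np.asarray(cfg.peak.offset_mm, dtype=np.float64)

    return TrackingSequence(
        positions=positions,
        joint_names=joint_names,
        frame_indices=np.arange(cfg.n_frames),
        fps=cfg.fps,
    )


def default_static_pose(
    pelvis: tuple[float, float, float] = (0.0, 150.0, 1900.0)
) -> dict[str, tuple[float, float, float]]:
    """A plausible standing pose for all 32 joints, mm in camera space.

    Camera-space axes: x right, y down, z forward; the subject stands
    ~1.9 m in front of the camera.  Proportions approximate a 1.72 m
    mannequin; only the rough geometry matters for the metrics, which are
    translation- and rotation-invariant.
    """
    px, py, pz = pelvis
    # heights (y is DOWN, so smaller y = higher in space)
    pose: dict[str, tuple[float, float, float]] = {
        "PELVIS": (px, py, pz),
        "SPINE_NAVEL": (px, py - 150.0, pz),
        "SPINE_CHEST": (px, py - 320.0, pz),
        "NECK": (px, py - 520.0, pz),
        "HEAD": (px, py - 640.0, pz),
        "NOSE": (px, py - 660.0, pz - 90.0),
        "EYE_LEFT": (px + 30.0, py - 680.0, pz - 80.0),
        "EYE_RIGHT": (px - 30.0, py - 680.0, pz - 80.0),
        "EAR_LEFT": (px + 70.0, py - 670.0, pz - 20.0),
        "EAR_RIGHT": (px - 70.0, py - 670.0, pz - 20.0),
    }
    for side, sx in (("LEFT", 1.0), ("RIGHT", -1.0)):
        pose[f"CLAVICLE_{side}"] = (px + sx * 60.0, py - 500.0, pz)
        pose[f"SHOULDER_{side}"] = (px + sx * 190.0, py - 490.0, pz)
        pose[f"ELBOW_{side}"] = (px + sx * 230.0, py - 210.0, pz + 10.0)
        pose[f"WRIST_{side}"] = (px + sx * 250.0, py + 40.0, pz - 20.0)
        pose[f"HAND_{side}"] = (px + sx * 255.0, py + 110.0, pz - 30.0)
        pose[f"HANDTIP_{side}"] = (px + sx * 258.0, py + 180.0, pz - 40.0)
        pose[f"THUMB_{side}"] = (px + sx * 225.0, py + 120.0, pz - 50.0)
        pose[f"HIP_{side}"] = (px + sx * 90.0, py + 20.0, pz)
        pose[f"KNEE_{side}"] = (px + sx * 100.0, py + 430.0, pz + 20.0)
        pose[f"ANKLE_{side}"] = (px + sx * 105.0, py + 830.0, pz + 40.0)
        pose[f"FOOT_{side}"] = (px + sx * 110.0, py + 880.0, pz - 90.0)
    # return in SDK order
    return {j: pose[j] for j in JOINT_NAMES}
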