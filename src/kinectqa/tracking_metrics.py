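"""Joint-jitter metrics for static-pose body-tracking sequences.

The central quantity is the **mean distance error (MDE)**: for each joint
a centroid trajectory is formed by a symmetric moving average over
2N+1 frames (N defaults to the frame rate, 30), the per-frame Euclidean
distance between the joint position and its centroid is taken, and the
distances are averaged over the analyzed frames.  For a static pose the
MDE measures the intensity of the tracker's positional noise; it is a
precision metric, not an accuracy-versus-ground-truth metric.

At the sequence ends the averaging window is clipped to the available
frames and, by default, normalized by the clipped window's actual size
(``end_mode="clip"``); ``end_mode="full"`` keeps the 1/(2N+1) divisor,
which biases end-of-sequence centroids toward the origin and exists only
for comparison.

The first 60 frames of a recording show converging tracker behavior and
are removed with :func:`cut_frames` before computing metrics.

The inter-joint distance series (e.g. left–right ankle: stance width in a
static pose, step width in gait) shares the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import TrackingSequence
from .joints import ANALYSIS_JOINTS

__all__ = [
    "CentroidSeries",
    "MDEResult",
    "DistanceSeries",
    "cut_frames",
    "sliding_centroid",
    "distance_to_centroid",
    "compute_mde",
    "joint_pair_distance",
    "five_number_summary",
]


@dataclass
class CentroidSeries:
    """Sliding-window centroid trajectory of one joint."""

    joint: str
    values: np.ndarray  # (n_frames, 3) mm
    half_width: int
    frame_indices: np.ndarray


@dataclass
class MDEResult:
    """Mean distance error per joint plus its per-frame distance series."""

    mde: dict[str, float]  # joint -> mm
    series: dict[str, np.ndarray]  # joint -> per-frame distances, mm
    half_width: int
    analyzed_frame_range: tuple[int, int]  # original frame indices [first, last]
    median: float  # across the joint selection
    q1: float
    q3: float

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


@dataclass
class DistanceSeries:
    """Per-frame Euclidean distance between two joints, with summary."""

    joint_a: str
    joint_b: str
    distances: np.ndarray  # (n_frames,) mm
    summary: "FiveNumberSummary"


@dataclass(frozen=True)
class FiveNumberSummary:
    """Boxplot statistics: min, q1, median, q3, max (mm)."""

    min: float
    q1: float
    median: float
    q3: float
    max: float


def five_number_summary(values: np.ndarray) -> FiveNumberSummary:
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot summarize an empty series")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return FiveNumberSummary(
        min=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(values.max()),
    )


def cut_frames(seq: TrackingSequence, n_cut: int = 60) -> TrackingSequence:
    """Drop the first *n_cut* stored frames (the convergence window).

    Original frame indices are retained, so downstream outputs stay
    traceable to the recording's frame numbering.
    """
    if n_cut < 0:
        raise ValueError("n_cut must be >= 0")
    if n_cut >= len(seq):
        raise ValueError(f"cutting {n_cut} frames of a {len(seq)}-frame sequence leaves nothing")
    if n_cut == 0:
        return seq
    return TrackingSequence(
        positions=seq.positions[n_cut:].copy(),
        joint_names=seq.joint_names,
        frame_indices=seq.frame_indices[n_cut:].copy(),
        fps=seq.fps,
        timestamps_usec=None
        if seq.timestamps_usec is None
        else seq.timestamps_usec[n_cut:].copy(),
        gap_frames=seq.gap_frames,
    )


def _sliding_mean(values: np.ndarray, half_width: int, end_mode: str) -> np.ndarray:
    """Symmetric moving average along axis 0 with clipped end windows.

    values: (n, ...) -> (n, ...).  end_mode "clip" divides each window by
    its actual length; "full" always divides by 2*half_width + 1.
    """
    n = values.shape[0]
    cumsum = np.cumsum(values, axis=0, dtype=np.float64)
    zero = np.zeros((1,) + values.shape[1:], dtype=np.float64)
    cumsum = np.concatenate([zero, cumsum], axis=0)  # cumsum[i] = sum of first i
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width, n - 1)
    window_sum = cumsum[hi + 1] - cumsum[lo]
    if end_mode == "clip":
        counts = (hi - lo + 1).astype(np.float64)
    elif end_mode == "full":
        counts = np.full(n, 2.0 * half_width + 1.0)
    else:
        raise ValueError("end_mode must be 'clip' or 'full'")
    shape = (n,) + (1,) * (values.ndim - 1)
    return window_sum / counts.reshape(shape)


def sliding_centroid(
    seq: TrackingSequence,
    joint: str,
    half_width: int = 30,
    end_mode: str = "clip",
) -> CentroidSeries:
    """Per-frame centroid of *joint*: mean position over frames [t−N, t+N].

    The window is clipped to the analyzed range at the sequence ends.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    traj = seq.joint_positions(joint)
    values = _sliding_mean(traj, half_width, end_mode)
    return CentroidSeries(
        joint=joint,
        values=values,
        half_width=half_width,
        frame_indices=seq.frame_indices.copy(),
    )


def distance_to_centroid(
    seq: TrackingSequence,
    centroids: CentroidSeries,
    squared: bool = False,
) -> np.ndarray:
    """Per-frame Euclidean distance (mm) of a joint to its centroid.

    ``squared=True`` returns squared distances (mm²), the literal
    no-square-root variant.
    """
    if centroids.values.shape[0] != len(seq) or not np.array_equal(
        centroids.frame_indices, seq.frame_indices
    ):
        raise ValueError("centroid series is not aligned with the sequence frames")
    diff = seq.joint_positions(centroids.joint) - centroids.values
    sq = np.einsum("ij,ij->i", diff, diff)
    return sq if squared else np.sqrt(sq)


def compute_mde(
    seq: TrackingSequence,
    joints: Sequence[str] | None = None,
    half_width: int = 30,
    end_mode: str = "clip",
    squared: bool = False,
) -> MDEResult:
    """Mean distance error per joint, plus median/IQR across the selection.

    *joints* defaults to the 18-joint analysis set intersected with the
    sequence's joint set.  The sequence is assumed to be already cut
    (see :func:`cut_frames`).
    """
    if joints is None:
        joints = [j for j in ANALYSIS_JOINTS if j in seq.joint_names]
    joints = list(joints)
    if not joints:
        raise ValueError("empty joint selection")
    mde: dict[str, float] = {}
    series: dict[str, np.ndarray] = {}
    for joint in joints:
        cents = sliding_centroid(seq, joint, half_width=half_width, end_mode=end_mode)
        dist = distance_to_centroid(seq, cents, squared=squared)
        series[joint] = dist
        mde[joint] = float(dist.mean())
    values = np.array(list(mde.values()))
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return MDEResult(
        mde=mde,
        series=series,
        half_width=half_width,
        analyzed_frame_range=(int(seq.frame_indices[0]), int(seq.frame_indices[-1])),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def joint_pair_distance(
    seq: TrackingSequence,
    joint_a: str,
    joint_b: str,
    squared: bool = False,
) -> DistanceSeries:
    """Per-frame distance between two joints with boxplot summary.

    For the ankle pair in a static pose this is the stance width.
    """
    if joint_a == joint_b:
        raise ValueError("joint_pair_distance requires two distinct joints")
    diff = seq.joint_positions(joint_a) - seq.joint_positions(joint_b)
    sq = np.einsum("ij,ij->i", diff, diff)
    dist = sq if squared else np.sqrt(sq)
    return DistanceSeries(
        joint_a=joint_a,
        joint_b=joint_b,
        distances=dist,
        summary=five_number_summary(dist),
    )
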