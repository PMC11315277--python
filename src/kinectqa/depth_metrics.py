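"""Per-pixel random error of repeated depth measurements over a static scene.

For each pixel p in a region of interest the random error is the root
mean squared deviation of its depth samples from their mean, computed
over the analyzed frames (after cutting the initial convergence window)::

    re[p] = sqrt( sum_t (d[p,t] - mean_p)^2 / n )

Invalid samples (sentinel value, no usable measurement) are excluded from
both the mean and the sum.  By default the divisor n is the number of
*valid* samples of that pixel, so a pixel valid in a single frame has
re = 0 and a pixel with no valid sample is undefined; ``denominator=
"analyzed"`` instead divides by the fixed number of analyzed frames (the
literal fixed-denominator variant), which deflates re for pixels with
many dropouts.  The variance is the population form (÷n, not ÷(n−1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DepthFrameStack, RegionOfInterest

__all__ = [
    "RandomErrorMap",
    "DepthSummary",
    "compute_random_error",
    "count_invalid",
    "summarize_random_error",
    "largest_square_roi",
]


@dataclass
class RandomErrorMap:
    """Per-pixel random error (mm) over one ROI; NaN marks undefined pixels."""

    region: RegionOfInterest
    re: np.ndarray  # (height, width) float, NaN where valid_count == 0
    valid_count: np.ndarray  # (height, width) int
    analyzed_frame_range: tuple[int, int]  # [start, end) in 0-based frame indices
    n_invalid_values: int = 0

    @property
    def n_analyzed_frames(self) -> int:
        return self.analyzed_frame_range[1] - self.analyzed_frame_range[0]

    def defined_values(self) -> np.ndarray:
        """1-D array of re values over pixels with at least one valid sample."""
        return self.re[~np.isnan(self.re)]


@dataclass(frozen=True)
class DepthSummary:
    """Five-number summary of a random-error map, mm."""

    min: float
    max: float
    median: float
    q1: float
    q3: float
    n_pixels_defined: int
    n_invalid_values: int

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("summary order statistics out of order")


def _analyzed_window(stack: DepthFrameStack, cut: int) -> tuple[int, int]:
    if cut < 0:
        raise ValueError("cut must be >= 0")
    if cut >= stack.n_frames:
        raise ValueError(
            f"cut of {cut} frames leaves no analyzed frames (stack has {stack.n_frames})"
        )
    return cut, stack.n_frames


def compute_random_error(
    stack: DepthFrameStack,
    roi: RegionOfInterest,
    cut: int = 60,
    denominator: str = "valid",
) -> RandomErrorMap:
    """Random error per pixel of *roi* over frames ``[cut, n_frames)``.

    Parameters
    ----------
    cut
        Number of initial frames to drop (convergence window), default 60.
    denominator
        ``"valid"`` (default): mean and divisor use each pixel's valid
        samples only.  ``"analyzed"``: divisor is the fixed analyzed-frame
        count regardless of dropouts (mean still over valid samples).
    """
    if denominator not in ("valid", "analyzed"):
        raise ValueError("denominator must be 'valid' or 'analyzed'")
    start, end = _analyzed_window(stack, cut)
    roi.check_inside(stack.height, stack.width)
    rs, cs = roi.slices
    sub = stack.frames[start:end, rs, cs].astype(np.float64)
    valid = sub != stack.invalid_sentinel
    n_valid = valid.sum(axis=0)
    n_invalid = int(valid.size - valid.sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.where(valid, sub, 0.0).sum(axis=0)
        mean = total / n_valid
        sq = np.where(valid, (sub - mean[None, :, :]) ** 2, 0.0).sum(axis=0)
        if denominator == "valid":
            re = np.sqrt(sq / n_valid)
        else:
            re = np.sqrt(sq / (end - start))
    re[n_valid == 0] = np.nan
    return RandomErrorMap(
        region=roi,
        re=re,
        valid_count=n_valid.astype(np.int64),
        analyzed_frame_range=(start, end),
        n_invalid_values=n_invalid,
    )


def count_invalid(stack: DepthFrameStack, roi: RegionOfInterest, cut: int = 60) -> int:
    """Total sentinel-valued samples over analyzed frames × ROI pixels."""
    start, end = _analyzed_window(stack, cut)
    roi.check_inside(stack.height, stack.width)
    rs, cs = roi.slices
    return int((stack.frames[start:end, rs, cs] == stack.invalid_sentinel).sum())


def summarize_random_error(error_map: RandomErrorMap) -> DepthSummary:
    """Order statistics over defined pixels; quartiles by linear interpolation."""
    values = error_map.defined_values()
    if values.size == 0:
        raise ValueError("all pixels undefined; nothing to summarize")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return DepthSummary(
        min=float(values.min()),
        max=float(values.max()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_pixels_defined=int(values.size),
        n_invalid_values=error_map.n_invalid_values,
    )


def largest_square_roi(mask: np.ndarray, name: str = "roi") -> RegionOfInterest:
    """Largest square of True pixels in a boolean mask, as a ROI.

    Dynamic-programming largest-square; ties resolve to the top-left-most
    square.  Mirrors the manual procedure of maximizing a square area on
    the object without including other regions.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be 2-D with at least one True pixel")
    h, w = mask.shape
    side = np.zeros((h, w), dtype=np.int64)
    best = (0, 0, 0)  # size, row, col of bottom-right corner
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            if r == 0 or c == 0:
                side[r, c] = 1
            else:
                side[r, c] = 1 + min(side[r - 1, c], side[r, c - 1], side[r - 1, c - 1])
            if side[r, c] > best[0]:
                best = (int(side[r, c]), r, c)
    size, r, c = best
    return RegionOfInterest(
        name=name, row_start=r - size + 1, col_start=c - size + 1, height=size, width=size
    )
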