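"""Nonparametric comparison protocol across recordings or lighting conditions.

The protocol mirrors common practice for non-normal pixel-level metrics:

1. screen each group for normality (Kolmogorov–Smirnov with estimated
   parameters, i.e. Lilliefors; a fixed-parameter KS variant is exposed),
2. an omnibus rank test — Kruskal–Wallis for independent groups
   (different lighting conditions), Friedman for related samples (the
   same pixels across repeated recordings),
3. if the omnibus test is significant at α, pairwise post-hoc z-tests on
   ranks with Bonferroni multiplication over all pairs (Dunn's test for
   the independent case, the within-block rank-sum analogue for the
   repeated case).

Observations (pixels) are treated as independent; spatial correlation
between neighbouring pixels is a known caveat of that reading and is not
corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairwiseResult",
    "ComparisonResult",
    "normality_screen",
    "compare_independent",
    "compare_repeated",
]


@dataclass(frozen=True)
class PairwiseResult:
    """One Bonferroni-adjusted post-hoc comparison."""

    group_a: str
    group_b: str
    statistic: float  # z value on mean ranks
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    """Omnibus test outcome plus (when significant) the pairwise table."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    groups: list[str]
    pairwise: list[PairwiseResult] | None = None
    n_dropped_rows: int = 0  # repeated-measures rows removed for missingness

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def normality_screen(
    samples: Sequence[np.ndarray],
    alpha: float = 0.05,
    method: str = "lilliefors",
) -> list[dict]:
    """KS-type normality p-value per group; flags non-normal groups.

    ``method="lilliefors"`` (default) estimates mean/SD from the data and
    uses the Lilliefors-corrected null distribution; ``method="ks"`` runs
    the fixed-parameter KS test against N(mean, SD) with the estimates
    plugged in (anticonservative, provided for comparison with tools that
    do this).
    """
    from statsmodels.stats.diagnostic import lilliefors

    out = []
    for i, sample in enumerate(samples):
        values = np.asarray(sample, dtype=np.float64).ravel()
        if values.size < 4:
            raise ValueError(f"group {i}: need n >= 4 for a normality screen")
        if method == "lilliefors":
            stat, p = lilliefors(values, dist="norm")
        elif method == "ks":
            stat, p = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
        else:
            raise ValueError("method must be 'lilliefors' or 'ks'")
        out.append(
            {"group": i, "statistic": float(stat), "p_value": float(p),
             "nonnormal": bool(p <= alpha)}
        )
    return out


def _bonferroni(p: float, n_comparisons: int) -> float:
    return float(min(1.0, p * n_comparisons))


def _dunn_pairwise(
    groups: list[np.ndarray], labels: list[str], alpha: float
) -> list[PairwiseResult]:
    """Dunn's z-tests on mean ranks with a tie-corrected pooled variance."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    offset = 0
    for size in sizes:
        mean_ranks.append(ranks[offset : offset + size].mean())
        offset += size
    # tie correction: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = _bonferroni(p, n_pairs)
            results.append(
                PairwiseResult(
                    group_a=labels[i],
                    group_b=labels[j],
                    statistic=float(z),
                    p_raw=float(p),
                    p_adjusted=p_adj,
                    significant=bool(p_adj <= alpha),
                )
            )
    return results


def compare_independent(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Tie-corrected Kruskal–Wallis omnibus with Dunn/Bonferroni post-hocs.

    Post-hoc pairwise comparisons are run only when the omnibus test is
    significant at *alpha*.
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for the omnibus comparison")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i}: need n >= 2")
    if labels is None:
        labels = [f"group_{i}" for i in range(len(groups))]
    labels = list(labels)
    if len(labels) != len(groups):
        raise ValueError("labels and groups disagree on length")
    if all(np.array_equal(groups[0], g) for g in groups[1:]):
        # identical groups: H = 0 by definition; scipy raises on all-tied data
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups)
    result = ComparisonResult(
        test_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        groups=labels,
    )
    if result.significant:
        result.pairwise = _dunn_pairwise(groups, labels, alpha)
    return result


def _friedman_pairwise(
    ranks: np.ndarray, labels: list[str], alpha: float
) -> list[PairwiseResult]:
    """Pairwise z-tests on mean within-block ranks (repeated measures)."""
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = _bonferroni(p, n_pairs)
            results.append(
                PairwiseResult(
                    group_a=labels[i],
                    group_b=labels[j],
                    statistic=float(z),
                    p_raw=float(p),
                    p_adjusted=p_adj,
                    significant=bool(p_adj <= alpha),
                )
            )
    return results


def compare_repeated(
    blocks: np.ndarray,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Tie-corrected Friedman omnibus with Bonferroni rank-sum post-hocs.

    *blocks* is an (n_rows × n_treatments) matrix — e.g. pixels × repeated
    recordings.  Rows containing NaN are dropped and counted in
    ``n_dropped_rows``.
    """
    blocks = np.asarray(blocks, dtype=np.float64)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D matrix (rows × treatments)")
    n_rows, k = blocks.shape
    if k < 3:
        raise ValueError("need at least 3 related samples (columns)")
    complete = ~np.isnan(blocks).any(axis=1)
    n_dropped = int(n_rows - complete.sum())
    blocks = blocks[complete]
    if blocks.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows after dropping missing values")
    if labels is None:
        labels = [f"treatment_{i}" for i in range(k)]
    labels = list(labels)
    if len(labels) != k:
        raise ValueError("labels and columns disagree on length")
    row_ranks = stats.rankdata(blocks, axis=1)
    if np.allclose(row_ranks, row_ranks[:, :1]):
        stat, p = 0.0, 1.0  # every row fully tied
    else:
        stat, p = stats.friedmanchisquare(*(blocks[:, i] for i in range(k)))
    result = ComparisonResult(
        test_name="friedman",
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        groups=labels,
        n_dropped_rows=n_dropped,
    )
    if result.significant:
        result.pairwise = _friedman_pairwise(row_ranks, labels, alpha)
    return result
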