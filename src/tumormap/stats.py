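"""Heterogeneity statistics.

Kruskal–Wallis rank ANOVA compares per-lesion pixel-intensity distributions
(and per-lesion vascular densities grouped by organ) without normality
assumptions. The tie-corrected statistic is

    H = [ 12/(N(N+1)) · Σ_i R_i²/n_i − 3(N+1) ] / C,
    C = 1 − Σ_t (t³ − t) / (N³ − N)  over tie groups of size t,

with mid-ranks over the pooled sample and an upper-tail chi-square p-value
on k − 1 degrees of freedom. Because whole-lesion pixel samples run to
millions of values (where any test rejects), a seeded uniform subsample
(default 10 000 pixels per lesion) bounds both runtime and p-value
degeneracy; full-sample mode is a parameter away.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import IntensityHistogram
from .types import TumorMapError

__all__ = [
    "SampleGroup",
    "KWResult",
    "kruskal_wallis",
    "subsample_pixels",
    "boxplot_summary",
]

ALPHA = 0.05
DEFAULT_N_MAX = 10_000

FLAG_ALL_TIES = "degenerate: all ties"


@dataclass
class SampleGroup:
    """One group of real values entering a rank test."""

    group_id: object
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size < 1:
            raise TumorMapError(f"group {self.group_id!r} is empty")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    k: int
    n_total: int
    tie_correction: float
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def kruskal_wallis(groups: Sequence[SampleGroup]) -> KWResult:
    """Tie-corrected Kruskal–Wallis test across k ≥ 2 groups.

    If every pooled value is identical the tie correction C is 0 and the
    result is defined as H = 0, p = 1 with a degenerate-ties flag.
    """
    k = len(groups)
    if k < 2:
        raise TumorMapError(f"Kruskal–Wallis needs ≥ 2 groups, got {k}")
    pooled = np.concatenate([g.values for g in groups])
    N = pooled.size
    if N < k + 1:
        raise TumorMapError(f"Kruskal–Wallis needs N ≥ k + 1 (N={N}, k={k})")
    ranks = sps.rankdata(pooled)  # mid-ranks for ties

    _, tie_sizes = np.unique(pooled, return_counts=True)
    C = 1.0 - float(np.sum(tie_sizes**3 - tie_sizes)) / (N**3 - N)
    df = k - 1
    if C == 0.0:
        return KWResult(0.0, df, 1.0, k, int(N), 0.0, (FLAG_ALL_TIES,))

    start = 0
    rank_sum_sq = 0.0
    for g in groups:
        r = ranks[start : start + g.n]
        start += g.n
        rank_sum_sq += float(r.sum()) ** 2 / g.n
    H = (12.0 / (N * (N + 1)) * rank_sum_sq - 3.0 * (N + 1)) / C
    H = max(H, 0.0)
    p = float(sps.chi2.sf(H, df))
    return KWResult(float(H), df, p, k, int(N), C)


def subsample_pixels(
    values: IntensityHistogram | Iterable[float],
    n_max: int = DEFAULT_N_MAX,
    seed: int = 0,
    group_id: object = None,
) -> SampleGroup:
    """Seeded uniform subsample without replacement, capped at ``n_max``.

    Accepts either raw values or an :class:`IntensityHistogram`, whose exact
    per-level pixel counts are reconstructed before sampling. Groups at or
    under ``n_max`` are returned whole; the result is deterministic for a
    fixed seed.
    """
    if n_max < 1:
        raise TumorMapError("n_max must be ≥ 1")
    if isinstance(values, IntensityHistogram):
        counts = np.rint(values.bins * values.n_pixels / 100.0).astype(np.int64)
        arr = np.repeat(np.arange(256, dtype=float), counts)
        if group_id is None:
            group_id = values.roi_id
    else:
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         float).ravel()
    if arr.size <= n_max:
        return SampleGroup(group_id, arr)
    rng = np.random.default_rng(seed)
    picked = rng.choice(arr.size, size=n_max, replace=False)
    return SampleGroup(group_id, arr[picked])


def boxplot_summary(groups: Sequence[SampleGroup]) -> pd.DataFrame:
    """Five-number summaries with Tukey whiskers, one row per group.

    Quartiles use linear interpolation (type 7); whiskers extend to the most
    extreme points within Q1 − 1.5·IQR and Q3 + 1.5·IQR; points beyond are
    counted as outliers.
    """
    rows = []
    for g in groups:
        v = g.values
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        rows.append({
            "group_id": g.group_id,
            "n": g.n,
            "min": float(v.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(v.max()),
            "whisker_lo": float(inside.min()),
            "whisker_hi": float(inside.max()),
            "n_outliers": int(v.size - inside.size),
        })
    return pd.DataFrame(rows)
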