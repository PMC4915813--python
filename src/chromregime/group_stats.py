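"""Directional rank-sum comparisons of promoter enrichment across
differential-expression groups, with the star significance annotation.

For every track, six one-sided Wilcoxon rank-sum tests are reported:
up vs unchanged, down vs unchanged and down vs up, each in both the
"greater" and "less" direction — matching a boxplot display where bars
above denote significantly higher and bars below significantly lower
signal. Stars: p <= 0.01 one, p <= 0.001 two, p <= 0.0001 three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

GROUPS = ("up", "down", "unchanged")
COMPARISON_PAIRS = (("up", "unchanged"), ("down", "unchanged"), ("down", "up"))
STAR_THRESHOLDS = (0.01, 0.001, 0.0001)

#: Exact enumeration is used at or below this combined sample size (tie-free).
EXACT_LIMIT = 12


@dataclass(frozen=True)
class GroupComparison:
    """One directional rank-sum comparison between two gene groups."""

    track: str
    group_a: str
    group_b: str
    direction: str  # 'greater': group_a tends larger than group_b
    statistic: float
    p_value: float
    stars: int
    n_a: int
    n_b: int


def wilcoxon_rank_sum(
    x, y, direction: str = "greater"
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    Exact enumeration when the combined sample size is <= 12 with no ties;
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(U statistic, p value)`` where U counts (x, y) pairs with
    x > y (+ half-ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if direction not in {"greater", "less"}:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        x, y, alternative=direction, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def star_annotation(p_value: float) -> int:
    """Significance stars: 3 if p <= 0.0001, 2 if p <= 0.001, 1 if p <= 0.01."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    stars = 0
    for threshold in STAR_THRESHOLDS:
        if p_value <= threshold:
            stars += 1
    return stars


def compare_groups(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    tracks: list[str] | None = None,
) -> pd.DataFrame:
    """Run the six directional comparisons per track.

    ``scores`` has a ``gene_id`` column plus one numeric column per track
    (typically the normalized enrichment of the gene's representative
    promoter); ``labels`` has ``gene_id`` and ``group`` (up/down/unchanged).
    Genes present in both tables are used. Returns one row per
    (track, pair, direction) with the statistic, p-value, stars and group
    sizes.
    """
    merged = scores.merge(labels[["gene_id", "group"]], on="gene_id")
    if tracks is None:
        tracks = [
            c for c in scores.columns
            if c != "gene_id" and pd.api.types.is_numeric_dtype(scores[c])
        ]
    for group in GROUPS:
        n = int((merged["group"] == group).sum())
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        if n < 3:
            warnings.warn(
                f"group {group!r} has only {n} genes; p-values are coarse",
                RuntimeWarning,
                stacklevel=2,
            )
    rows = []
    for track, (ga, gb), direction in product(
        tracks, COMPARISON_PAIRS, ("greater", "less")
    ):
        a = merged.loc[merged["group"] == ga, track].to_numpy()
        b = merged.loc[merged["group"] == gb, track].to_numpy()
        stat, p = wilcoxon_rank_sum(a, b, direction)
        rows.append(
            GroupComparison(
                track=track, group_a=ga, group_b=gb, direction=direction,
                statistic=stat, p_value=p, stars=star_annotation(p),
                n_a=len(a), n_b=len(b),
            )
        )
    return pd.DataFrame([vars(c) for c in rows])
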