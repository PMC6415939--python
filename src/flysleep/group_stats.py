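"""Nonparametric group comparisons for per-fly metrics.

The comparison layer used throughout the pipeline: Mann-Whitney U for two
groups, Kruskal-Wallis with Dunn's post-hoc z-tests for three or more, and
Bonferroni adjustment over the requested comparison family.  Dunn's test is
computed on the pooled tie-corrected ranks:

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) · (1/n_i + 1/n_j) ),

with tie term T = Σ(t³ − t) / (12(N − 1)) over tie groups of size t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "bonferroni_adjust",
    "significance_stars",
]

#: pooled-sample size at or below which the exact Mann-Whitney null is used
EXACT_MWU_MAX_N = 16


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    comparison: tuple[str, ...]
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def significance_stars(p: float) -> str:
    """Significance markers as used in the figure legends."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Uses the exact null when the pooled sample is small (n_a + n_b <=
    16) and tie-free, and the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MWU_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test_name=f"mann-whitney-u ({method})",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        comparison=labels,
        n_per_group=(int(a.size), int(b.size)),
    )


def _dunn_z(groups: Mapping[str, np.ndarray], pair: tuple[str, str]) -> tuple[float, int, int]:
    order = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in order]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g, s in zip(order, samples):
        mean_rank[g] = float(ranks[start : start + s.size].mean())
        start += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    gi, gj = pair
    ni, nj = groups[gi].size, groups[gj].size
    se = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
    if se == 0.0:  # all observations tied
        return 0.0, ni, nj
    z = (mean_rank[gi] - mean_rank[gj]) / se
    return float(z), ni, nj


def kruskal_wallis_dunn(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    correction: str = "bonferroni",
) -> tuple[GroupComparison, list[GroupComparison]]:
    """Tie-corrected Kruskal-Wallis omnibus plus Dunn's pairwise post-hoc.

    ``comparisons`` lists the requested pairs (default: all pairs); the
    Bonferroni family is exactly that list.
    """
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_dunn requires >= 3 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if v.size < 2:
            warnings.warn(f"group {g!r} has < 2 observations", stacklevel=2)
    names = list(arrays)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for pair in comparisons:
        if pair[0] not in arrays or pair[1] not in arrays:
            raise KeyError(f"comparison {pair} references an unknown group")

    try:
        h_stat, h_p = stats.kruskal(*arrays.values())
    except ValueError:
        h_stat, h_p = 0.0, 1.0
    if not (np.isfinite(h_stat) and np.isfinite(h_p)):
        # every observation identical: no rank variation, trivially null
        h_stat, h_p = 0.0, 1.0
    omnibus = GroupComparison(
        test_name="kruskal-wallis",
        statistic=float(h_stat),
        p_raw=float(h_p),
        p_adjusted=float(h_p),
        comparison=tuple(names),
        n_per_group=tuple(int(v.size) for v in arrays.values()),
    )

    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    m = len(comparisons)
    posthoc = []
    for pair in comparisons:
        z, ni, nj = _dunn_z(arrays, pair)
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        posthoc.append(
            GroupComparison(
                test_name="dunn",
                statistic=z,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
                comparison=pair,
                n_per_group=(int(ni), int(nj)),
            )
        )
    return omnibus, posthoc


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p·m capped at 1, order preserved."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in p_values]
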