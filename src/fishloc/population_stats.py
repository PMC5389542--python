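"""Population summaries and significance tests for per-cell scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PopulationSummary",
    "summarize",
    "mann_whitney_two_tailed",
    "fisher_exact_fraction_positive",
    "welch_t_two_tailed",
]


@dataclass(frozen=True)
class PopulationSummary:
    n: int
    median_tos: float
    mean_tos: float
    sem: float
    fraction_positive: float
    single_observation: bool = False


def summarize(values) -> PopulationSummary:
    """Median / mean / SEM / fraction strictly positive.

    SEM uses the n-1 denominator sample standard deviation.  A single
    observation has no SEM; it is reported as 0 with a flag.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    n = values.size
    single = n == 1
    sem = 0.0 if single else float(values.std(ddof=1) / np.sqrt(n))
    return PopulationSummary(
        n=int(n),
        median_tos=float(np.median(values)),
        mean_tos=float(values.mean()),
        sem=sem,
        fraction_positive=float(np.count_nonzero(values > 0) / n),
        single_observation=single,
    )


def mann_whitney_two_tailed(a, b) -> float:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration of the U distribution for small, tie-free samples
    (both sizes <= 20); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size <= 20 and b.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def fisher_exact_fraction_positive(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> float:
    """Two-tailed Fisher's exact test on a 2x2 table of (positive,
    non-positive) counts per group."""
    table = np.array([group_a, group_b], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table[0].sum() < 1 or table[1].sum() < 1:
        raise ValueError("each group must have at least one observation")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def welch_t_two_tailed(a, b) -> float:
    """Two-tailed Welch (unequal variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
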