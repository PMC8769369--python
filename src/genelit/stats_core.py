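"""Shared statistical primitives.

Everything downstream — journal/funder enrichment scans, sliding-window share
series, citation percentiles — is built on a handful of primitives that are
implemented here once so that every stage uses identical conventions:

* a two-sided Fisher exact test defined by the probability-mass rule,
* Bonferroni family-wise control with an inclusive threshold,
* percentile-bootstrap confidence intervals,
* Spearman rank correlation with average ranks for ties,
* within-cohort midrank percentiles (used for "top 5% of its year" flags).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata

__all__ = [
    "ContingencyTable",
    "BootstrapCI",
    "fisher_exact_two_sided",
    "bonferroni_reject",
    "bootstrap_ci",
    "spearman",
    "cohort_percentile",
    "cohort_percentiles",
]

#: relative slack on the "probability <= observed" comparison, absorbing
#: floating-point noise in the hypergeometric mass
_TWO_SIDED_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in-group & target, b = in-group & non-target,
    c = out-group & target, d = out-group & non-target."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval.

    ``point_outside`` is raised (not an error) when the full-sample statistic
    lies outside its own percentile interval, which can happen for strongly
    skewed statistics.
    """

    point: float
    lo: float
    hi: float
    level: float = 0.95
    n_boot: int = 1000
    seed: int = 0

    @property
    def point_outside(self) -> bool:
        return not (self.lo <= self.point <= self.hi)


def _fisher_from_counts(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TWO_SIDED_RTOL)].sum())
    return min(p, 1.0)


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return _fisher_from_counts(a, b, c, d)


def fisher_exact_two_sided(table: ContingencyTable | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p-value under the probability-mass rule.

    Sums hypergeometric probabilities of every table with the observed margins
    whose probability is at most that of the observed table (with relative
    slack 1e-7 on the comparison).  Raises ``ValueError`` when a row or column
    margin is zero, where the conditional test is undefined.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("Fisher exact test undefined: zero row or column margin")
    return _fisher_cached(a, b, c, d)


def bonferroni_reject(pvals: Sequence[float], alpha: float = 0.01) -> list[bool]:
    """Reject H0_i iff p_i <= alpha / m, with m the number of tests in the scan.

    The threshold comparison is inclusive, so a single test with p exactly
    equal to alpha is rejected.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = len(pvals)
    if m == 0:
        return []
    thresh = alpha / m
    return [p <= thresh for p in pvals]


_STAT_FUNCS: dict[str, Callable[..., np.ndarray]] = {
    "mean": np.mean,
    "share": np.mean,  # share of a 0/1 indicator is its mean
    "median": np.median,
}


def bootstrap_ci(
    values,
    statistic: str | Callable = "mean",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI, resampling the rows of ``values``.

    The resampling unit is whatever one row represents; callers pass
    publication-level rows when the paper-style interval "over publications"
    is wanted.  Deterministic for a given ``seed``.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    stat = _STAT_FUNCS.get(statistic, statistic) if isinstance(statistic, str) else statistic
    if isinstance(statistic, str) and statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    if stat in (np.mean, np.median) and values.ndim == 1:
        boots = stat(values[idx], axis=1)
    else:
        boots = np.array([stat(values[idx[i]]) for i in range(n_boot)], dtype=float)
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(boots, [tail, 100.0 - tail])
    return BootstrapCI(
        point=float(stat(values)), lo=float(lo), hi=float(hi),
        level=level, n_boot=n_boot, seed=seed,
    )


def spearman(x, y) -> float:
    """Rank correlation with average ranks for ties.

    Computed as the Pearson correlation of the midrank-transformed samples.
    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def cohort_percentile(value: float, cohort) -> float:
    """Midrank percentile of ``value`` within its cohort.

    percentile = 100 * (members strictly below + half the ties) / cohort size.
    The cohort must contain the member being scored (its tie counts itself).
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.size == 0:
        raise ValueError("empty cohort")
    below = np.count_nonzero(cohort < value)
    ties = np.count_nonzero(cohort == value)
    return 100.0 * (below + 0.5 * ties) / cohort.size


def cohort_percentiles(values) -> np.ndarray:
    """Vectorised midrank percentile of every member within the same cohort."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.empty(0)
    # average rank r gives below + 0.5*ties = r - 0.5
    ranks = rankdata(values)
    return 100.0 * (ranks - 0.5) / values.size
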