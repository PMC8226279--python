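"""Shared statistical kernels with exact small-sample behaviour.

Every network comparison in the pipeline reduces to one of three classical
tests: the two-sample Wilcoxon rank-sum (Mann-Whitney), the paired Wilcoxon
signed-rank, and Fisher's exact test on a 2x2 table. Small samples are
handled by exact enumeration (via scipy's exact methods), larger ones by the
tie-corrected normal approximation; which route was taken is recorded in the
result so downstream tables can report it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "wilcoxon_rank_sum", "wilcoxon_signed_rank",
           "fisher_exact_2x2"]

#: largest per-group n for which the rank-sum test is enumerated exactly
RANK_SUM_EXACT_MAX_N = 25
#: largest n for which the signed-rank test is enumerated exactly
SIGNED_RANK_EXACT_MAX_N = 20


@dataclass(frozen=True, slots=True)
class TestResult:
    """Outcome of a hypothesis test, with provenance of the computation."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    exact: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both samples are tie-free and the smaller has at
    most ``RANK_SUM_EXACT_MAX_N`` observations; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical, no evidence either way
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                          method="rank-sum", n=(x.size, y.size), exact=True,
                          note="all observations identical")
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and min(x.size, y.size) <= RANK_SUM_EXACT_MAX_N
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if use_exact else "asymptotic")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="rank-sum", n=(x.size, y.size), exact=use_exact,
                      note="" if use_exact else "normal approximation, tie-corrected")


def wilcoxon_signed_rank(d, alternative: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test on differences ``d``.

    Zero differences are dropped (their count is recorded); exact sign-pattern
    enumeration up to ``SIGNED_RANK_EXACT_MAX_N`` tie-free differences.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("difference vector must be non-empty")
    nonzero = d[d != 0]
    n_dropped = d.size - nonzero.size
    note = f"{n_dropped} zero differences dropped" if n_dropped else ""
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="signed-rank",
                          n=(d.size,), exact=True,
                          note="all differences zero")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    use_exact = (not has_ties) and nonzero.size <= SIGNED_RANK_EXACT_MAX_N
    res = sps.wilcoxon(nonzero, alternative=alternative,
                       method="exact" if use_exact else "approx")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="signed-rank", n=(d.size,), exact=use_exact,
                      note=note if use_exact else
                      "; ".join(s for s in (note, "normal approximation") if s))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table (hypergeometric tails)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("contingency table cells must be nonnegative")
    res = sps.fisher_exact(table, alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="fisher-exact", n=tuple(int(v) for v in table.sum(axis=1)),
                      exact=True)
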