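"""Rank-based two-sample testing shared by the comparison stages.

Every group contrast in the pipeline (expression level, expression breadth,
Ka/Ks, region methylation) is a two-sided Mann-Whitney U test; p-values are
reported raw, without multiple-testing correction, each labelled with its
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: combined sample size at or below which the exact null distribution is used
EXACT_LIMIT = 12


@dataclass
class TestResult:
    u_statistic: float  # U of sample a
    p_value: float
    n_a: int
    n_b: int
    method: str  # 'exact' or 'normal_approx'
    median_a: float | None = None
    median_b: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    The exact null enumeration is used when ``n_a + n_b <= EXACT_LIMIT`` and
    there are no ties; otherwise the normal approximation with tie-corrected
    variance and continuity correction is used.  Two identical samples give
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            u_statistic=a.size * b.size / 2.0,
            p_value=1.0,
            n_a=a.size,
            n_b=b.size,
            method="degenerate",
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
        )
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_LIMIT and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return TestResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        method=method,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the figure-legend star convention (strict cutoffs)."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def comparison_row(name: str, result: TestResult) -> dict:
    """Serializable record for the consolidated comparisons table."""
    return {
        "comparison": name,
        "n_a": result.n_a,
        "n_b": result.n_b,
        "U": result.u_statistic,
        "p": result.p_value,
        "stars": result.stars,
        "median_a": result.median_a,
        "median_b": result.median_b,
    }
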