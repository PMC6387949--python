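"""Inferential statistics used in the results pipeline.

Thin, explicit wrappers over scipy/statsmodels: paired t, Wilcoxon
signed-rank (continuity-corrected normal approximation, zeros dropped,
midranks for ties), Pearson correlation, and Benjamini-Hochberg FDR
adjustment. All tests are two-sided by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "pearson",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p: float
    df: float | None = None
    n: int | None = None


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Paired t test on matched sequences; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.std(d) == 0:
        # degenerate: identical differences; t is 0 (no effect) or +-inf
        if d[0] == 0:
            return TestResult("paired_t", 0.0, 1.0, df=float(n - 1), n=n)
        stat = np.inf if d[0] > 0 else -np.inf
        return TestResult("paired_t", float(stat), 0.0, df=float(n - 1), n=n)
    res = sps.ttest_rel(x, y)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                      df=float(n - 1), n=n)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Wilcoxon signed-rank via continuity-corrected normal approximation.

    Zero differences are dropped (Wilcoxon's rule); ties get midranks.
    All-zero differences are undefined and raise explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: statistic undefined")
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                       method="approx", alternative="two-sided")
    # report Z signed by the direction of the effect (positive when x > y)
    dz = d[d != 0]
    ranks = sps.rankdata(np.abs(dz))
    direction = 1.0 if ranks[dz > 0].sum() >= ranks[dz < 0].sum() else -1.0
    z = direction * abs(float(res.zstatistic))
    return TestResult("wilcoxon_signed_rank", z, float(res.pvalue),
                      n=int(dz.size))


def pearson(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Product-moment correlation; two-sided p from the t transform
    with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("sequences must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), float(p), df=float(len(x) - 2),
                      n=len(x))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
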