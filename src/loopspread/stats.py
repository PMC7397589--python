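"""Shared statistics kernel: Fisher exact, Wilcoxon tests, BH correction.

Every enrichment or group comparison in the package routes through these
functions so that the exact-test conventions (two-sided conditional Fisher p,
Pratt handling of zero differences, Haldane odds-ratio correction, step-up BH)
are applied uniformly and are validated in one place against enumeration
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    flag: str = ""       # "all-zero", "insufficient-data", ...


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided conditional Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p).  The p-value is the hypergeometric sum of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  The odds ratio is the sample OR with a Haldane 0.5
    correction applied when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return sample_odds_ratio(t), float(p)


def sample_odds_ratio(table) -> float:
    t = np.asarray(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def log_odds_ratio(table) -> float:
    return float(np.log(sample_odds_ratio(table)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (paired) and rank-sum
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic.

    `ranks2` are the doubled ranks (integers even with midranks); `w2` the
    doubled observed positive-rank sum.  The null distribution is over all
    2^n equiprobable sign assignments, built by polynomial convolution.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(w2))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x, y=None, exact_below_n: int = 25) -> TestResult:
    """Paired signed-rank test with Pratt treatment of zero differences.

    Zeros are ranked together with the non-zero |differences| and then
    discarded; midranks are used for ties.  The exact null (conditional on
    the realized ranks) is used for n <= `exact_below_n`, a tie- and
    zero-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    n = len(d)
    if n == 0:
        raise ValueError("empty sample")
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "signed-rank", flag="all-zero")

    ranks = sps.rankdata(np.abs(d))          # zeros included (Pratt)
    nz = d != 0
    w_plus = float(ranks[d > 0].sum())

    if nz.sum() <= exact_below_n:
        ranks2 = np.round(2 * ranks[nz]).astype(int)
        p = _signed_rank_exact_p(ranks2, 2 * w_plus)
        return TestResult(w_plus, p, "signed-rank-exact")

    # normal approximation with Pratt zero correction and tie correction
    n_all = float(n)
    n_zero = float(n - nz.sum())
    mu = (n_all * (n_all + 1) / 4.0) - n_zero * (n_zero + 1) / 4.0
    var = (n_all * (n_all + 1) * (2 * n_all + 1) / 24.0
           - n_zero * (n_zero + 1) * (2 * n_zero + 1) / 24.0)
    _, counts = np.unique(ranks[nz], return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "signed-rank-approx", flag="degenerate-variance")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w_plus, float(min(1.0, p)), "signed-rank-approx")


def wilcoxon_rank_sum(x, y, exact_below_n: int = 25) -> TestResult:
    """Two-sample Mann-Whitney/Wilcoxon rank-sum test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_below_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), f"rank-sum-{method}")


def wilcoxon_tests(x, y=None, mode: str = "signed-rank", exact_below_n: int = 25) -> TestResult:
    if mode == "signed-rank":
        if y is not None and len(np.asarray(x)) != len(np.asarray(y)):
            raise ValueError("paired test requires equal lengths")
        return wilcoxon_signed_rank(x, y, exact_below_n)
    if mode == "rank-sum":
        return wilcoxon_rank_sum(x, y, exact_below_n)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
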