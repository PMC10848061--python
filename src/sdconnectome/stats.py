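"""Group-comparison statistics used throughout the analysis.

Two-sample pooled-variance (Student) t tests — from raw samples or from
printed summary statistics (mean +/- SD, n) — chi-square for 2x2 tables
without continuity correction, tie-corrected Wilcoxon rank-sum Z,
Benjamini-Hochberg FDR, and Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    tails: str  # "one" or "two"
    method: str


def pooled_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Student two-sample t from group summaries (pooled variance).

    t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)) with
    s_p^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2),
    df = n_a + n_b - 2, two-tailed p. Reproduces t values printed from
    mean +/- SD tables. Both SDs zero: t = 0 for equal means, +/-inf
    (flagged by the value itself) otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if sp2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        p = 2 * sps.t.sf(abs(t), df)
    return TestResult(t, float(df), float(p), "two", "pooled_t")


def two_sample_t(samples_a, samples_b) -> TestResult:
    """Pooled two-sample t from raw samples (identical to the summary form)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return pooled_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square for a 2x2 count table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be nonnegative integers")
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square undefined")
    ntot = t.sum()
    num = ntot * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2
    chi2 = num / np.prod(margins)
    return TestResult(float(chi2), 1.0, float(sps.chi2.sf(chi2, 1)), "two", "chi_square")


def rank_sum_z(samples_a, samples_b) -> TestResult:
    """Wilcoxon rank-sum with midranks and tie-corrected normal approximation.

    Z = (W - E[W]) / sqrt(Var[W]) where W is the rank sum of sample a,
    E[W] = n_a (n+1) / 2 and the variance carries the tie correction
    Var[W] = n_a n_b / 12 * (n + 1 - sum(t^3 - t) / (n (n - 1))).
    Two-tailed p from the normal distribution; Z = 0 when every value ties.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = ranks[:n_a].sum()
    ew = n_a * (n + 1) / 2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(0.0, None, 1.0, "two", "rank_sum")
    z = (w - ew) / math.sqrt(var)
    return TestResult(float(z), None, float(2 * sps.norm.sf(abs(z))), "two", "rank_sum")


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman(x, y) -> TestResult:
    """Spearman rank correlation: Pearson on midranks, p by t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(x.size - 2), float(p), "two", "spearman")


def one_tailed_p(result: TestResult, direction: str = "greater") -> float:
    """One-tailed p for a symmetric two-tailed test result.

    direction refers to the sign of the statistic: "greater" tests
    statistic > 0, "less" tests statistic < 0.
    """
    half = result.p_value / 2
    pos = result.statistic >= 0
    if (direction == "greater") == pos:
        return half
    return 1 - half
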