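"""Core statistics: exact 2x2 and binomial tests, rank-sum engine, fold
ratios, empirical p-values, BH correction, and the non-centrality-based
power / cohort-size projection.

The two-sided rules follow the minimum-likelihood convention: a two-sided
p-value sums the probabilities of all outcomes no more likely than the
observed one.  For the balanced binomial (p0 = 0.5) this equals doubling
the smaller exact tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Table2x2:
    """Counts (rows = groups, columns = outcome yes/no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")
        if (self.a + self.b == 0) or (self.c + self.d == 0) \
                or (self.a + self.c == 0) or (self.b + self.d == 0):
            raise ValueError("empty margin")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    sidedness: str  # "one" | "two"
    method: str


@dataclass(frozen=True)
class PowerQuery:
    """Inputs to the cohort-size projection.

    ``power_current`` is the detection power of the current study of
    effective size ``n_current`` at two-sided level ``alpha_two_sided``;
    ``power_target`` is the power the projected cohort should reach.
    """

    alpha_two_sided: float = 5e-8
    power_current: float = 0.5
    n_current: float = 1.0
    power_target: float = 0.8

    def __post_init__(self) -> None:
        for p in (self.power_current, self.power_target):
            if not 0 < p < 1:
                raise ValueError("power values must be in (0, 1)")
        if not 0 < self.alpha_two_sided < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_current <= 0:
            raise ValueError("n_current must be > 0")


def fisher_exact(table: Table2x2, sidedness: str = "two") -> TestResult:
    """Exact hypergeometric test on a 2x2 table.

    One-sided tests the tail of the observed direction (enrichment of the
    first group's outcome rate relative to the second); two-sided uses the
    minimum-likelihood rule.
    """
    t = [[table.a, table.b], [table.c, table.d]]
    if sidedness == "two":
        odds, p = sps.fisher_exact(t, alternative="two-sided")
    elif sidedness == "one":
        rate1 = table.a / (table.a + table.b)
        rate2 = table.c / (table.c + table.d)
        alt = "greater" if rate1 >= rate2 else "less"
        odds, p = sps.fisher_exact(t, alternative=alt)
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    return TestResult(float(odds), float(p), sidedness, "fisher_exact")


def fold_ratio(k1: int, n1: int, k2: int, n2: int) -> float:
    """Ratio of proportions (k1/n1) / (k2/n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if k2 == 0:
        raise ZeroDivisionError("undefined fold: zero numerator in reference rate")
    return (k1 / n1) / (k2 / n2)


def binomial_exact(k: int, n: int, p0: float, sidedness: str = "two") -> TestResult:
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if sidedness == "two":
        p = sps.binomtest(k, n, p0).pvalue
    elif sidedness == "one":
        alt = "greater" if k >= n * p0 else "less"
        p = sps.binomtest(k, n, p0, alternative=alt).pvalue
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    return TestResult(float(k), float(min(p, 1.0)), sidedness, "binomial_exact")


def rank_sum(
    group_a: np.ndarray, group_b: np.ndarray, sidedness: str = "two",
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test.

    Exact null enumeration when ``len(a)*len(b) <= 400`` and the pooled
    sample is tie-free; otherwise the tie-corrected normal approximation
    with continuity correction.  ``alternative`` follows scipy semantics
    and is only consulted when ``sidedness == 'one'``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if sidedness == "two":
        alternative = "two-sided"
    elif alternative == "two-sided":
        raise ValueError("one-sided test needs alternative 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      sidedness, f"mann_whitney_{method}")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Permutation p-value with the +1 correction; never 0."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("need at least one null value")
    return float((1 + np.count_nonzero(null_values >= observed))
                 / (1 + null_values.size))


def required_n_for_power(q: PowerQuery) -> dict[str, float]:
    """Project the cohort size needed to reach a target power.

    Model: the association z-statistic is Normal(NCP, 1) with NCP
    proportional to sqrt(n).  The current NCP is recovered from the
    current power at the two-sided level alpha (neglecting the far tail):
    ``NCP = z_{alpha/2} - Phi^{-1}(1 - power)``; the target NCP is
    ``z_{alpha/2} + Phi^{-1}(power_target)``; the required n scales with
    the squared NCP ratio.
    """
    z_half = sps.norm.isf(q.alpha_two_sided / 2)
    ncp_current = z_half - sps.norm.isf(q.power_current)
    if ncp_current <= 0:
        raise ValueError(
            "current power is at or below the alpha-implied floor; "
            "NCP is not identifiable"
        )
    ncp_target = z_half + sps.norm.ppf(q.power_target)
    n_raw = q.n_current * (ncp_target / ncp_current) ** 2
    return {
        "ncp_current": float(ncp_current),
        "ncp_target": float(ncp_target),
        "n_required": float(n_raw),
        "n_required_rounded": float(round(n_raw / 100) * 100),
    }


def power_at_ncp(ncp: float, alpha_two_sided: float = 5e-8) -> float:
    """Two-sided detection power of a Normal(ncp, 1) z-statistic."""
    z_half = sps.norm.isf(alpha_two_sided / 2)
    return float(sps.norm.sf(z_half - ncp) + sps.norm.cdf(-z_half - ncp))


def bayes_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed posterior interval for a proportion, uniform prior.

    Beta(k+1, n-k+1) posterior; a convenience helper, not calibrated to
    any particular published interval.
    """
    lo = (1 - level) / 2
    dist = sps.beta(k + 1, n - k + 1)
    return float(dist.ppf(lo)), float(dist.ppf(1 - lo))
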