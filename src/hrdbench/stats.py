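"""Inferential toolkit for the cohort analysis.

Covers binomial proportion intervals (continuity-corrected Wilson score
by default — the closed form that reproduces the published Table 1
bounds), the partially overlapping samples z-test for dichotomous
variables (two proportions compared when some tumors are observed under
both conditions and some under only one, with the paired block's phi
correlation correcting the pooled variance), pairwise one-sided Fisher
exact tests with Bonferroni adjustment, and Spearman correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

CI_METHODS = ("wilson_cc", "wilson", "clopper_pearson")


@dataclass(frozen=True)
class ProportionEstimate:
    successes: int
    trials: int
    proportion: float
    lower: float
    upper: float
    level: float
    method: str


@dataclass(frozen=True)
class OverlapSamples:
    """Dichotomous outcomes under two conditions with partial overlap.

    ``paired`` holds (outcome_a, outcome_b) for tumors observed under
    both conditions; ``only_a`` / ``only_b`` hold outcomes of tumors
    observed under a single condition.
    """

    paired: Sequence[tuple[bool, bool]]
    only_a: Sequence[bool]
    only_b: Sequence[bool]

    def __post_init__(self):
        if not (len(self.paired) or len(self.only_a) or len(self.only_b)):
            raise ValueError("all three observation blocks are empty")


def _wilson_cc(k: int, n: int, level: float) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval (Newcombe's closed form)."""
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 2 * (n + z * z)
    if k == 0:
        lower = 0.0
    else:
        lower = (2 * n * p + z * z - 1
                 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    if k == n:
        upper = 1.0
    else:
        upper = (2 * n * p + z * z + 1
                 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    return max(0.0, lower), min(1.0, upper)


def proportion_ci(
    k: int, n: int, method: str = "wilson_cc", level: float = 0.95
) -> ProportionEstimate:
    """Binomial proportion with confidence interval.

    ``wilson_cc`` (default) is the continuity-corrected Wilson score
    interval; plain ``wilson`` and ``clopper_pearson`` are delegated to
    statsmodels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if method == "wilson_cc":
        lower, upper = _wilson_cc(k, n, level)
    elif method == "wilson":
        lower, upper = proportion_confint(k, n, alpha=1 - level, method="wilson")
    elif method == "clopper_pearson":
        lower, upper = proportion_confint(k, n, alpha=1 - level, method="beta")
    else:
        raise ValueError(f"unknown method {method!r}; use one of {CI_METHODS}")
    return ProportionEstimate(
        successes=k, trials=n, proportion=k / n,
        lower=float(lower), upper=float(upper), level=level, method=method,
    )


def overlap_z_test(
    data: OverlapSamples, alternative: str = "greater"
) -> tuple[float, float]:
    """Partially overlapping samples z-test for two proportions.

    The statistic compares P(outcome | condition a) with
    P(outcome | condition b) using every observation, with the pooled
    variance reduced by twice the paired-block phi correlation term:

        z = (p_a - p_b) / sqrt( p(1-p) * (1/n_a + 1/n_b - 2*phi*c/(n_a*n_b)) )

    where c is the number of paired tumors and p the pooled proportion.
    With no paired block this reduces to the classical pooled
    two-proportion z-test. ``alternative`` is "greater" (a > b), "less",
    or "two-sided". All-identical outcomes report (0.0, 0.5) for the
    one-sided test (p = 1 for two-sided) — a degenerate, not an error.
    """
    paired = [(bool(a), bool(b)) for a, b in data.paired]
    xa_pair = sum(a for a, _ in paired)
    xb_pair = sum(b for _, b in paired)
    c = len(paired)
    only_a = [bool(v) for v in data.only_a]
    only_b = [bool(v) for v in data.only_b]
    n_a = c + len(only_a)
    n_b = c + len(only_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("each condition needs at least one observation")
    x_a = xa_pair + sum(only_a)
    x_b = xb_pair + sum(only_b)
    p_a, p_b = x_a / n_a, x_b / n_b
    pooled = (x_a + x_b) / (n_a + n_b)

    phi = 0.0
    if c >= 2:
        a11 = sum(a and b for a, b in paired)
        a10 = sum(a and not b for a, b in paired)
        a01 = sum(b and not a for a, b in paired)
        a00 = c - a11 - a10 - a01
        m = (a11 + a10) * (a01 + a00) * (a11 + a01) * (a10 + a00)
        if m > 0:
            phi = (a11 * a00 - a10 * a01) / math.sqrt(m)

    var = pooled * (1 - pooled) * (1 / n_a + 1 / n_b - 2 * phi * c / (n_a * n_b))
    if var <= 0:
        z = 0.0
    else:
        z = (p_a - p_b) / math.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def pairwise_fisher(
    groups: dict[str, tuple[int, int]],
    alternative: str = "two-sided",
    correction: str = "bonferroni",
) -> dict[tuple[str, str], dict[str, float]]:
    """All pairwise Fisher exact tests on (successes, failures) groups.

    Adjusted p = min(1, p * number_of_pairs) under Bonferroni. A pair
    containing a zero-total group gets NaN p values (undefined, not an
    error). Keys of the result are (group_i, group_j) in input order,
    testing group_i vs group_j with the given one-sided direction.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_pairs = len(pairs)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in pairs:
        (sa, fa), (sb, fb) = groups[a], groups[b]
        if sa + fa == 0 or sb + fb == 0:
            raw = adj = float("nan")
        else:
            raw = float(stats.fisher_exact([[sa, fa], [sb, fb]], alternative=alternative)[1])
            if correction == "bonferroni":
                adj = min(1.0, raw * n_pairs)
            elif correction in (None, "none"):
                adj = raw
            else:
                raise ValueError(f"unknown correction {correction!r}")
        out[(a, b)] = {"p_raw": raw, "p_adjusted": adj}
    return out


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Multiply each p by the family size, capping at 1."""
    m = len(p_values)
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in p_values]
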