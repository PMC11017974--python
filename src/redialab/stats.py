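"""Statistical primitives shared by the pattern battery.

The workhorse is a Wilcoxon/Mann-Whitney rank-sum test that switches between
an exhaustive permutation enumeration for small samples and the tie- and
continuity-corrected normal approximation otherwise, mirroring the behaviour
of the classical two-sample rank test as implemented in mainstream
statistical environments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RankSumResult",
    "ProportionCI",
    "rank_sum",
    "proportion_ci",
    "quartiles",
    "growth_trend",
]


@dataclass
class RankSumResult:
    U_statistic: float
    p_value: float
    alternative: str  # 'greater', 'less', 'two_sided' (first sample vs second)
    exact: bool
    n1: int
    n2: int


@dataclass
class ProportionCI:
    successes: int
    trials: int
    point: float
    lo: float
    hi: float
    level: float = 0.95

    def overlaps(self, other: "ProportionCI") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


def _u_statistic(ranks: np.ndarray, idx1: Sequence[int], n1: int) -> float:
    r1 = ranks[list(idx1)].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two_sided",
    exact_n_max: int = 12,
) -> RankSumResult:
    """Two-sample rank-sum test of ``group_a`` against ``group_b``.

    ``alternative='greater'`` tests whether ``group_a`` is stochastically
    larger than ``group_b``.  When the combined sample size is at most
    ``exact_n_max`` the p-value is computed by enumerating every assignment
    of the pooled observations to the two groups (exact even under ties,
    conditionally on the observed values); otherwise the normal approximation
    with midranks, tie-corrected variance and a 0.5 continuity correction is
    used.  The reported ``U_statistic`` is the Mann-Whitney U of ``group_a``.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two_sided'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    tie_free = np.unique(pooled).size == n

    if n <= exact_n_max:
        total = math.comb(n, n1)
        n_ge = n_le = 0
        for idx in combinations(range(n), n1):
            u = _u_statistic(ranks, idx, n1)
            if u >= u_obs - 1e-12:
                n_ge += 1
            if u <= u_obs + 1e-12:
                n_le += 1
        p_greater = n_ge / total
        p_less = n_le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return RankSumResult(u_obs, p, alternative, tie_free, n1, n2)

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # all observations identical: no evidence either way
        return RankSumResult(u_obs, 1.0, alternative, False, n1, n2)
    sigma = math.sqrt(sigma2)
    diff = u_obs - mu
    if alternative == "greater":
        z = (diff - 0.5) / sigma
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (diff + 0.5) / sigma
        p = sps.norm.cdf(z)
    else:
        z = (diff - math.copysign(0.5, diff)) / sigma if diff != 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankSumResult(u_obs, float(p), alternative, False, n1, n2)


def proportion_ci(
    successes: int,
    trials: int,
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> ProportionCI:
    """Exact (Clopper-Pearson) binomial confidence interval by default."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in 0..trials")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method=sm_method)
    return ProportionCI(successes, trials, successes / trials, float(lo), float(hi), level)


def quartiles(values: Sequence[float]) -> tuple[float, float]:
    """Q1 and Q3 by linear interpolation at index (n-1)p + 1 (type 7)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def growth_trend(
    days: Sequence[float], mean_lengths_um: Sequence[float]
) -> tuple[float, float]:
    """OLS slope (um/day) of mean redia length on time, with two-sided p.

    Used to ask whether rediae held in culture change length over the
    observation period.  Requires at least three timepoints.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(mean_lengths_um, dtype=float)
    if t.size != y.size:
        raise ValueError("days and mean_lengths_um must have equal length")
    if t.size < 3:
        raise ValueError("growth_trend requires at least 3 timepoints")
    if np.unique(t).size < 2:
        raise ValueError("timepoints must not be all identical")
    res = sps.linregress(t, y)
    p = res.pvalue
    if not np.isfinite(p):
        # perfect fit with nonzero slope: below machine resolution
        p = 0.0 if res.slope != 0 else 1.0
    return float(res.slope), float(p)
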