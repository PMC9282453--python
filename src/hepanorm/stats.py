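"""Statistical battery: Mann-Whitney U by sex, Pearson age correlation, OLS slope.

The Mann-Whitney implementation counts, over all cross-group pairs, wins plus
half-ties (equivalently: rank-sum minus its minimum).  For groups of at least
8 each, the p-value uses the normal approximation with tie-corrected variance
and a continuity correction; below that, the exact permutation distribution of
U given the pooled (possibly tied) values is enumerated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import Sex

__all__ = [
    "TestName",
    "Effect",
    "TestResult",
    "mann_whitney_u",
    "mann_whitney_gender",
    "pearson_age",
    "simple_linear_regression",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05
_EXACT_MAX_PER_GROUP = 7  # exact enumeration below 8 per group


class TestName(str, enum.Enum):
    MANN_WHITNEY_U = "mann_whitney_u"
    PEARSON = "pearson"
    LINEAR_REGRESSION = "linear_regression"


@dataclass(frozen=True)
class Effect:
    r: Optional[float] = None
    r_squared: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None


@dataclass(frozen=True)
class TestResult:
    test_name: TestName
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect: Optional[Effect] = None
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _near_constant(arr: np.ndarray, rel_tol: float = 1e-12) -> bool:
    """True when variation is at floating-point noise level."""
    return float(np.std(arr)) <= rel_tol * max(1.0, float(np.abs(arr).max(initial=0.0)))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: midrank-sum of x minus n1*(n1+1)/2; equals the all-pairs
    count of (x > y) plus half the ties."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_two_sided_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact permutation p-value of the two-sided U test under ties.

    Counts, over all ways of assigning n1 of the pooled values to group 1,
    the probability that U deviates from its null mean n1*n2/2 at least as
    much as observed.  The count is a dynamic programme over tied-value
    blocks on doubled midrank sums (doubling keeps half-integer midranks
    integral), so cost is polynomial rather than combinatorial.
    """
    n = pooled.size
    n2 = n - n1
    _, counts = np.unique(pooled, return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    double_midranks = 2 * starts + counts + 1  # block ranks s+1..s+m -> 2*midrank

    width = n1 * int(double_midranks.max(initial=0)) + 1
    dp = np.zeros((n1 + 1, width))
    dp[0, 0] = 1.0
    for m, dr in zip(counts.tolist(), double_midranks.tolist()):
        new = np.zeros_like(dp)
        for k in range(min(m, n1) + 1):
            ways = math.comb(m, k)
            shift = k * dr
            new[k:, shift:] += ways * dp[: n1 + 1 - k, : width - shift]
        dp = new
    dist = dp[n1]  # counts indexed by doubled group-1 rank sum

    double_u = np.arange(width) - n1 * (n1 + 1)  # 2*U for each doubled rank sum
    dev = abs(2.0 * u_obs - n1 * n2)
    hits = dist[np.abs(double_u - n1 * n2) >= dev - 1e-9].sum()
    return float(hits / dist.sum())


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U for the first group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("group values must be finite")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])

    if n1 <= _EXACT_MAX_PER_GROUP or n2 <= _EXACT_MAX_PER_GROUP:
        p = _exact_two_sided_p(pooled, n1, u)
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float((counts**3 - counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:  # all values identical
            p = 1.0
        else:
            mean = n1 * n2 / 2.0
            cc = 0.5 if u != mean else 0.0
            z = (abs(u - mean) - cc) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(z)
    return TestResult(
        test_name=TestName.MANN_WHITNEY_U,
        statistic=u,
        p_value=min(p, 1.0),
        n=(n1, n2),
        alpha=alpha,
    )


def mann_whitney_gender(
    values: Sequence[float], sexes: Sequence[Sex], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Compare a per-patient concentration between female and male patients.

    The reported U is that of the female group (first group).
    """
    values = np.asarray(values, dtype=float)
    sexes = list(sexes)
    if len(values) != len(sexes):
        raise ValueError("values and sexes must align")
    fem = values[[s is Sex.FEMALE or s == Sex.FEMALE for s in sexes]]
    mal = values[[s is Sex.MALE or s == Sex.MALE for s in sexes]]
    return mann_whitney_u(fem, mal, alpha=alpha)


def pearson_age(
    values: Sequence[float], ages: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Pearson correlation of a concentration with age; two-sided p via the
    t transform with n-2 degrees of freedom."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size != ages.size:
        raise ValueError("values and ages must align")
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if _near_constant(values) or _near_constant(ages):
        raise ValueError("degenerate input: zero variance")
    res = sps.pearsonr(ages, values)
    r = float(res.statistic)
    return TestResult(
        test_name=TestName.PEARSON,
        statistic=r,
        p_value=float(res.pvalue),
        n=(values.size,),
        effect=Effect(r=r, r_squared=r * r),
        alpha=alpha,
    )


def simple_linear_regression(
    values: Sequence[float], ages: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Ordinary least squares of concentration on age (slope in mg/ml per year)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size != ages.size:
        raise ValueError("values and ages must align")
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if _near_constant(ages):
        raise ValueError("degenerate design: all ages equal")
    res = sps.linregress(ages, values)
    r = float(res.rvalue)
    return TestResult(
        test_name=TestName.LINEAR_REGRESSION,
        statistic=float(res.slope),
        p_value=float(res.pvalue),
        n=(values.size,),
        effect=Effect(
            r=r, r_squared=r * r, slope=float(res.slope), intercept=float(res.intercept)
        ),
        alpha=alpha,
    )
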