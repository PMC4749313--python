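"""Robust two-sample and k-sample tests, plus simple linear regression.

The four procedures the copy-number analyses rely on, implemented from
first principles:

* :func:`fligner_policello_test` — the robust rank-order test for a
  difference in medians that assumes neither equal shapes nor equal
  variances between the two samples (Fligner & Policello 1981).
* :func:`fligner_policello_exact` — an exact permutation version used as
  the small-sample oracle for the asymptotic test.
* :func:`fligner_killeen_test` — the normal-scores test for homogeneity
  of variances across k groups, robust to non-normality.
* :func:`welch_t_test` — Welch's unequal-variance t test.
* :func:`ols_fit` — ordinary least squares of y on x with vertical
  residuals and their moments, the building block of the aCGH outlier
  statistic.

All p-values are two-sided and no multiple-testing correction is applied;
each comparison in the pipeline is reported raw.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "TestResult",
    "RegressionFit",
    "fligner_policello_test",
    "fligner_policello_exact",
    "fligner_killeen_test",
    "welch_t_test",
    "ols_fit",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is the standardized z for the robust rank-order test,
    chi-square for Fligner-Killeen, t for Welch, and the observed z for
    the exact permutation test. ``degenerate`` flags results where a
    variance term in the denominator collapsed to zero; ``reason``
    explains why.
    """

    method: str
    statistic: float
    p_value: float
    n_groups: tuple[int, ...]
    df: float | None = None
    degenerate: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n_groups": list(self.n_groups),
            "degenerate": self.degenerate,
            "reason": self.reason,
        }


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS fit of a response on one predictor.

    Residuals are vertical (response minus fitted value); their standard
    deviation uses the n−1 denominator. With an intercept in the model
    the residual mean is zero up to floating-point error.
    """

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    residuals: np.ndarray = field(repr=False)
    residual_mean: float = 0.0
    residual_sd: float = 0.0

    @property
    def n(self) -> int:
        return len(self.residuals)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _as_sample(v, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < min_n:
        raise InputError(f"sample {name!r} needs >= {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"sample {name!r} contains non-finite values")
    return arr


def _placements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """P(x_i) = #{y_j < x_i} + ½·#{y_j = x_i} for each x_i."""
    xs = x[:, None]
    return np.sum(y[None, :] < xs, axis=1) + 0.5 * np.sum(y[None, :] == xs, axis=1)


def _fp_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Standardized robust rank-order statistic.

    Returns (z, degenerate). z > 0 when y tends to exceed x. Complete
    separation gives a zero denominator: z is ±inf when the placement
    sums differ, nan when both variability terms and the numerator are
    zero (identical constant samples).
    """
    n, m = len(x), len(y)
    px = _placements(x, y)  # counts of y below each x
    py = _placements(y, x)  # counts of x below each y
    # Conservation: every (x_i, y_j) pair contributes exactly 1 in total.
    assert math.isclose(px.sum() + py.sum(), n * m), "placement conservation violated"
    pbar_x = px.mean()
    pbar_y = py.mean()
    vx = float(np.sum((px - pbar_x) ** 2))
    vy = float(np.sum((py - pbar_y) ** 2))
    num = py.sum() - px.sum()
    den = 2.0 * math.sqrt(vx + vy + pbar_x * pbar_y)
    if den == 0.0:
        if num == 0.0:
            return math.nan, True
        return math.copysign(math.inf, num), True
    return num / den, False


def fligner_policello_test(x, y) -> TestResult:
    """Robust rank-order test for equality of medians of two samples.

    Uses placements (counts of the other sample's values below each
    observation, ties counted one half) and their variability indices;
    the standardized statistic is referred to the standard normal for a
    two-sided p-value. Positive z means ``y`` tends larger than ``x``.

    Complete separation makes the denominator vanish; the result is then
    flagged degenerate with p = 0 (p = 1 if the samples are identical
    constants), so pipelines can continue and report the flag.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    z, degenerate = _fp_statistic(xa, ya)
    if degenerate:
        if math.isnan(z):
            return TestResult("fligner_policello", math.nan, 1.0, (len(xa), len(ya)),
                              degenerate=True, reason="zero numerator and denominator")
        return TestResult("fligner_policello", z, 0.0, (len(xa), len(ya)),
                          degenerate=True,
                          reason="complete separation: zero variability indices")
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("fligner_policello", z, min(p, 1.0), (len(xa), len(ya)))


def fligner_policello_exact(x, y, max_total: int = 14) -> TestResult:
    """Exact permutation version of the robust rank-order test.

    Enumerates every reassignment of the pooled values into groups of
    the observed sizes and reports the proportion whose |z| is at least
    the observed |z| (infinite |z| from separated relabelings counts as
    at least any finite |z|). Feasible only for small samples; the
    default bound n+m <= 14 caps enumeration at C(14,7)=3432 splits.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    n, m = len(xa), len(ya)
    if n + m > max_total:
        raise InputError(
            f"n+m={n + m} exceeds exact enumeration bound {max_total}; "
            "use a Monte-Carlo permutation approach instead")
    z_obs, _ = _fp_statistic(xa, ya)
    abs_obs = abs(z_obs) if not math.isnan(z_obs) else 0.0
    pooled = np.concatenate([xa, ya])
    idx = range(n + m)
    count = 0
    total = 0
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        z, _ = _fp_statistic(pooled[mask], pooled[~mask])
        a = abs(z) if not math.isnan(z) else 0.0
        # >= with a small tolerance so the observed split always counts
        if a >= abs_obs - 1e-12:
            count += 1
        total += 1
    return TestResult("permutation", z_obs if not math.isnan(z_obs) else 0.0,
                      count / total, (n, m))


def fligner_killeen_test(groups) -> TestResult:
    """Fligner-Killeen normal-scores test for homogeneity of variances.

    Each group is centered at its median; the pooled absolute deviations
    are ranked (midranks for ties) and transformed to normal scores
    a_i = Φ⁻¹(½ + r_i / (2(N+1))). The statistic
    Σ_j n_j (Ā_j − ā)² / s², with s² the sample variance of all scores,
    is referred to chi-square with k−1 degrees of freedom.
    """
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    arrs = [_as_sample(g, f"group {j}", min_n=2) for j, g in enumerate(groups)]
    sizes = tuple(len(a) for a in arrs)
    devs = np.concatenate([np.abs(a - np.median(a)) for a in arrs])
    if np.all(devs == 0.0):
        return TestResult("fligner_killeen", 0.0, 1.0, sizes, df=float(len(arrs) - 1),
                          degenerate=True, reason="all absolute deviations zero")
    big_n = devs.size
    ranks = sps.rankdata(devs)  # midranks for ties
    scores = sps.norm.ppf(0.5 + ranks / (2.0 * (big_n + 1.0)))
    abar = scores.mean()
    s2 = scores.var(ddof=1)
    stat = 0.0
    pos = 0
    for nj in sizes:
        gbar = scores[pos:pos + nj].mean()
        stat += nj * (gbar - abar) ** 2
        pos += nj
    stat /= s2
    df = float(len(arrs) - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult("fligner_killeen", float(stat), p, sizes, df=df)


def welch_t_test(x, y) -> TestResult:
    """Welch's two-sample t test with Satterthwaite degrees of freedom."""
    xa = _as_sample(x, "x", min_n=2)
    ya = _as_sample(y, "y", min_n=2)
    n, m = len(xa), len(ya)
    vx = xa.var(ddof=1)
    vy = ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        equal = xa.mean() == ya.mean()
        return TestResult("welch_t", 0.0 if equal else math.inf,
                          1.0 if equal else 0.0, (n, m),
                          degenerate=True, reason="both samples constant")
    se2 = vx / n + vy / m
    t = (xa.mean() - ya.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("welch_t", float(t), min(p, 1.0), (n, m), df=float(df))


def ols_fit(x, y) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` with an intercept.

    Returns the fitted slope and intercept, R², the two-sided p-value of
    the slope from the t distribution with n−2 degrees of freedom, and
    the vertical residuals with their mean and (n−1) standard deviation.
    """
    xa = _as_sample(x, "x", min_n=3)
    ya = _as_sample(y, "y", min_n=3)
    if xa.size != ya.size:
        raise InputError(f"x and y differ in length ({xa.size} vs {ya.size})")
    if np.ptp(xa) == 0.0:
        raise InputError("x is constant: regression design is degenerate")
    n = xa.size
    xbar, ybar = xa.mean(), ya.mean()
    sxx = float(np.sum((xa - xbar) ** 2))
    if sxx == 0.0:  # ptp > 0 can still underflow to a zero sum of squares
        raise InputError("x is numerically constant: regression design is degenerate")
    sxy = float(np.sum((xa - xbar) * (ya - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = ya - (intercept + slope * xa)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((ya - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0.0 else 1.0
    if n > 2 and rss > 0.0:
        se_slope = math.sqrt(rss / (n - 2) / sxx)
        t = slope / se_slope
        p_slope = 2.0 * float(sps.t.sf(abs(t), n - 2))
    else:
        p_slope = 0.0 if slope != 0.0 else 1.0
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        p_slope=min(p_slope, 1.0),
        residuals=resid,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)) if n > 1 else 0.0,
    )
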