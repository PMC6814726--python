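"""Psychophysics statistics for dominance data.

Group summaries (mean dominance and SEM across observers), two-sided
paired t-tests with Holm correction and Cohen's d with a
noncentral-t confidence interval, and power / sample-size computation
for the paired t-test via the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedComparison",
    "dominance_summary",
    "paired_test",
    "holm_adjust",
    "power_paired_t",
    "min_n_for_power",
    "cohens_d_ci",
]


def _nct_cdf(x: float, df: int, nc: float) -> float:
    """Noncentral-t CDF, robust to the NaNs scipy can return deep in a
    tail; a NaN that survives the complement fallback is a tail
    underflow and resolves by the side of the noncentrality."""
    v = float(stats.nct.cdf(x, df, nc))
    if math.isnan(v):
        v = 1.0 - float(stats.nct.sf(x, df, nc))
    if math.isnan(v):
        v = 0.0 if x < nc else 1.0
    return min(max(v, 0.0), 1.0)


def _nct_sf(x: float, df: int, nc: float) -> float:
    v = float(stats.nct.sf(x, df, nc))
    if math.isnan(v):
        v = 1.0 - float(stats.nct.cdf(x, df, nc))
    if math.isnan(v):
        v = 1.0 if x < nc else 0.0
    return min(max(v, 0.0), 1.0)


def dominance_summary(per_observer: pd.DataFrame) -> pd.DataFrame:
    """Group mean dominance and SEM across observers, per condition.

    ``per_observer`` needs columns ``condition`` and ``dominance`` (one
    row per observer and condition); a ``report`` column, if present,
    is part of the grouping.  SEM uses the sample standard deviation
    (ddof=1) divided by sqrt(n observers); it is 0 for a single
    observer.
    """
    if len(per_observer) == 0:
        raise ValueError("need at least one observer")
    keys = [k for k in ("condition", "report") if k in per_observer.columns]
    if not keys:
        raise ValueError("need a 'condition' column")

    def agg(g: pd.Series) -> pd.Series:
        n = len(g)
        sem = float(g.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return pd.Series({"mean_dominance": g.mean(), "sem": sem, "n_observers": n})

    out = per_observer.groupby(keys, sort=False)["dominance"].apply(agg).unstack()
    out["n_observers"] = out["n_observers"].astype(int)
    return out.reset_index()


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test between two matched conditions.

    ``degenerate`` flags zero-variance differences, for which t, p and
    the CI are undefined.  ``p_adjusted`` is filled in by
    ``holm_adjust`` when the comparison is part of a family.
    """

    condition_a: str
    condition_b: str
    n: int
    df: int
    mean_diff: float
    t_statistic: float | None
    p_value: float | None
    cohens_d: float | None
    ci95: tuple[float, float] | None
    degenerate: bool = False
    p_adjusted: float | None = None


def cohens_d_ci(
    t: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """CI for a paired-design Cohen's d by noncentral-t pivot inversion.

    Finds the noncentrality parameters for which the observed t is the
    upper/lower tail quantile, then rescales by sqrt(n).  This is the
    convention of common effect-size software.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    alpha = 1.0 - confidence

    def solve(target_cdf: float) -> float:
        # nct.cdf(t; df, nc) is decreasing in nc; bracket around t and
        # widen until the root is enclosed
        from scipy.optimize import brentq

        f = lambda nc: _nct_cdf(t, df, nc) - target_cdf
        half = 10.0
        while f(t - half) * f(t + half) > 0:
            half *= 2.0
            if half > 1e6:
                raise RuntimeError("failed to bracket the noncentrality root")
        return brentq(f, t - half, t + half, xtol=1e-8)

    nc_lower = solve(1.0 - alpha / 2.0)
    nc_upper = solve(alpha / 2.0)
    return (nc_lower / math.sqrt(n), nc_upper / math.sqrt(n))


def paired_test(
    cond_a: np.ndarray | list[float], cond_b: np.ndarray | list[float],
    name_a: str = "a", name_b: str = "b",
) -> PairedComparison:
    """Two-sided paired t-test with effect size.

    Cohen's d for the paired design is mean(diff)/sd(diff) (so that
    d = t/sqrt(n)); the 95% CI comes from the noncentral-t pivot.
    Zero-variance differences are flagged degenerate instead of
    producing a p-value.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D matched samples")
    n = a.size
    if n < 2:
        raise ValueError("need at least two matched observers")
    diff = a - b
    sd = diff.std(ddof=1)
    mean = float(diff.mean())
    if sd == 0.0:
        if mean == 0.0:
            # identical samples: no effect at all
            return PairedComparison(
                condition_a=name_a, condition_b=name_b, n=n, df=n - 1,
                mean_diff=0.0, t_statistic=0.0, p_value=1.0, cohens_d=0.0,
                ci95=None,
            )
        # constant non-zero shift: sd(diff)=0, t undefined
        return PairedComparison(
            condition_a=name_a, condition_b=name_b, n=n, df=n - 1,
            mean_diff=mean, t_statistic=None, p_value=None, cohens_d=None,
            ci95=None, degenerate=True,
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    d = mean / sd
    return PairedComparison(
        condition_a=name_a, condition_b=name_b, n=n, df=n - 1,
        mean_diff=mean, t_statistic=float(t), p_value=float(p),
        cohens_d=float(d), ci95=cohens_d_ci(t, n),
    )


def holm_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Step-down Holm adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def power_paired_t(
    d: float, n: int, alpha: float = 0.05, tails: str = "two"
) -> float:
    """Power of a paired (one-sample) t-test at effect size d.

    The test statistic under the alternative is noncentral t with
    df = n - 1 and noncentrality d*sqrt(n); power is the probability
    of exceeding the two-sided (or one-sided) critical value.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    nc = d * math.sqrt(n)
    if tails == "two":
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return _nct_sf(t_crit, df, nc) + _nct_cdf(-t_crit, df, nc)
    if tails == "one":
        t_crit = stats.t.ppf(1.0 - alpha, df)
        return _nct_sf(t_crit, df, nc)
    raise ValueError("tails must be 'two' or 'one'")


def min_n_for_power(
    d: float, target_power: float, alpha: float = 0.05, tails: str = "two",
    n_max: int = 10_000,
) -> int:
    """Smallest number of observers reaching the target power."""
    if d <= 0:
        raise ValueError("d must be > 0")
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(d, n, alpha, tails) >= target_power:
            return n
    raise ValueError(f"target power {target_power} not reached by n = {n_max}")
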