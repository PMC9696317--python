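"""Replicate summaries and the two-sample t-test protocol used to compare
secondary-structure compositions against the 0-min control.

The independent two-sample test defaults to the pooled-variance Student's t;
Welch's unequal-variance variant is available since equal variances are an
assumption, not a given.  No multiple-testing correction is applied across
elements (each comparison is reported at alpha = 0.05 with its 95% CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sd: float | None
    se: float | None
    n: int

    def __str__(self):
        if self.sd is None:
            return f"{self.mean:.4g} (n=1, dispersion undefined)"
        return f"{self.mean:.4g} +- {self.sd:.4g} (SE {self.se:.4g}, n={self.n})"


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    reject_at_0_05: bool
    ci_95: tuple[float, float]
    variant: str = "pooled"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.reject_at_0_05 != (self.p_value < 0.05):
            raise ValueError("reject flag inconsistent with p-value")


def summarize(values) -> SampleSummary:
    """Sample mean, SD (n-1 denominator) and SE.  A single value yields an
    undefined (None) dispersion rather than an error."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    if arr.size == 1:
        return SampleSummary(mean=float(arr[0]), sd=None, se=None, n=1)
    sd = float(arr.std(ddof=1))
    return SampleSummary(mean=float(arr.mean()), sd=sd, se=sd / math.sqrt(arr.size), n=int(arr.size))


def two_sample_ttest(a, b, variant: str = "pooled") -> TTestResult:
    """Independent two-sample t-test (two-sided) with a 95% CI on mean(a) - mean(b).

    ``variant='pooled'`` assumes equal variances (classical Student's t);
    ``'welch'`` uses the Welch-Satterthwaite approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "pooled"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        df = se**4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)) if se > 0 else na + nb - 2
    diff = float(a.mean() - b.mean())
    if se > 0:
        tcrit = float(sps.t.ppf(0.975, df))
        ci = (diff - tcrit * se, diff + tcrit * se)
    else:
        # identical constant groups: degenerate but well-defined
        t, p, ci = 0.0, 1.0, (diff, diff)
    if math.isnan(t):
        t, p = 0.0, 1.0
    return TTestResult(
        t_statistic=t,
        degrees_of_freedom=float(df),
        p_value=p,
        reject_at_0_05=p < 0.05,
        ci_95=ci,
        variant=variant,
    )


def type_one_error_rate(
    n_per_group: int = 5,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the pooled test under H0 (both groups
    iid standard normal).  Should calibrate to ``alpha``."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    res = sps.ttest_ind(a, b, axis=1, equal_var=True)
    return float(np.mean(res.pvalue < alpha))
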