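"""Two-group statistical comparison of texture profiles.

For each of the seven histogram parameters, the two diet arms are compared
with a two-sample t-test whose variance assumption is chosen by a two-sided
F-test on the sample variances: equal variances not rejected at alpha →
pooled t-test; rejected → Welch's unequal-variance t-test. Percent change
is reported on the raw parameter scale, signed, relative to the first
(control) group. No multiple-testing correction is applied across the
seven parameters: each row carries its raw p-value.

Also provides the ordinary least-squares regression of the phantom's
per-insert Nakagami parameter on insert mineral density.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .texture import TextureProfile

__all__ = [
    "ComparisonRow",
    "DegenerateSampleError",
    "f_test_equal_variance",
    "two_sample_t",
    "percent_change",
    "compare_groups",
    "nakagami_density_regression",
]


class DegenerateSampleError(ValueError):
    """A sample is too small or has zero variance for the requested test."""


@dataclasses.dataclass(frozen=True)
class ComparisonRow:
    """One report line: per-group summary, p-value, percent change, test used."""

    parameter: str
    group_a_mean: float
    group_a_sd: float
    group_b_mean: float
    group_b_sd: float
    p_value: float
    percent_change: float
    test_variant: str  # "pooled" | "unequal-variance"


def _check_sample(x: Sequence[float], require_variance: bool = True) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise DegenerateSampleError(f"sample size {arr.size} < 2")
    if require_variance and np.var(arr, ddof=1) == 0:
        raise DegenerateSampleError("sample has zero variance")
    return arr


def f_test_equal_variance(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided variance-ratio F-test p-value, larger variance in numerator."""
    a = _check_sample(a)
    b = _check_sample(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return float(min(p, 1.0))


def two_sample_t(
    a: Sequence[float], b: Sequence[float], pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: (t, df, p).

    ``pooled`` selects the equal-variance statistic with df = n_a + n_b − 2;
    otherwise Welch's statistic with Satterthwaite degrees of freedom.
    """
    a = _check_sample(a, require_variance=False)
    b = _check_sample(b, require_variance=False)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        # identical constant samples: no evidence of a difference
        df = a.size + b.size - 2 if pooled else float(a.size + b.size - 2)
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else res.df
    return float(res.statistic), float(df), float(res.pvalue)


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change 100·(treated − control)/control."""
    if control_mean == 0:
        raise ZeroDivisionError("percent change undefined for zero control mean")
    return 100.0 * (treated_mean - control_mean) / control_mean


def compare_groups(
    profiles_a: Sequence[TextureProfile],
    profiles_b: Sequence[TextureProfile],
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """One ComparisonRow per texture parameter, F-test-gated t-test per row."""
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise DegenerateSampleError("need at least 2 profiles per group")
    rows = []
    for name in TextureProfile.PARAMETERS:
        xa = np.array([getattr(p, name) for p in profiles_a], dtype=float)
        xb = np.array([getattr(p, name) for p in profiles_b], dtype=float)
        identical = np.array_equal(np.sort(xa), np.sort(xb))
        if identical and np.var(xa, ddof=1) == 0:
            p_equal_var = 1.0
        else:
            p_equal_var = f_test_equal_variance(xa, xb)
        pooled = p_equal_var >= alpha
        _, _, p_value = two_sample_t(xa, xb, pooled=pooled)
        rows.append(
            ComparisonRow(
                parameter=name,
                group_a_mean=float(np.mean(xa)),
                group_a_sd=float(np.std(xa, ddof=1)),
                group_b_mean=float(np.mean(xb)),
                group_b_sd=float(np.std(xb, ddof=1)),
                p_value=p_value,
                percent_change=percent_change(float(np.mean(xa)), float(np.mean(xb))),
                test_variant="pooled" if pooled else "unequal-variance",
            )
        )
    return rows


def nakagami_density_regression(
    nakagami_values: Sequence[float], densities: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of Nakagami on insert density: (slope, intercept, r², slope-test p)."""
    y = np.asarray(nakagami_values, dtype=float)
    x = np.asarray(densities, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("regression undefined for constant inputs")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )
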