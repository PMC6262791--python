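"""Statistical layer: two-sample tests, variance F-test, Fisher's exact
test, box-plot summaries, and penetrance normalization.

All tests report two-sided p-values. Box-plot summaries follow the ggplot2
conventions: hinges are type-7 (linearly interpolated) quartiles, whiskers
extend to the most extreme data values within 1.5 * IQR of the hinges, and
everything beyond is an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "FTestResult",
    "FisherResult",
    "BoxplotSummary",
    "two_sample_t",
    "f_variance_test",
    "fisher_exact",
    "boxplot_summary",
    "contingency_fraction",
    "normalize_penetrance",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    equal_variance: bool
    defined: bool = True


@dataclass(frozen=True)
class FTestResult:
    F: float
    df: tuple[int, int]
    p_two_sided: float
    defined: bool = True


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    zero_margin: bool = False


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    lower_hinge: float
    upper_hinge: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...] = ()


def _as_group(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if len(arr) < 2:
        raise ValueError(f"group {name} needs at least 2 observations")
    return arr


def two_sample_t(a, b, equal_variance: bool = True) -> TTestResult:
    """Unpaired two-sample t-test, Student (pooled variance) or Welch.

    Student's version uses df = n_a + n_b - 2; Welch uses the
    Welch-Satterthwaite df and does not assume equal variances. When both
    groups have zero variance and equal means the statistic is undefined
    and the result is flagged rather than returned as a silent NaN.
    """
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        df = len(a) + len(b) - 2 if equal_variance else float("nan")
        return TTestResult(float("nan"), df, float("nan"), equal_variance, defined=False)
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    if equal_variance:
        df = float(len(a) + len(b) - 2)
    else:
        na, nb = len(a), len(b)
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = float(num / den)
    return TTestResult(float(res.statistic), df, float(res.pvalue), equal_variance)


def f_variance_test(a, b) -> FTestResult:
    """Two-sided F-test for equality of variances.

    F = s_a^2 / s_b^2 with (n_a - 1, n_b - 1) degrees of freedom;
    p = 2 * min(P(F <= f), P(F >= f)), capped at 1. Sensitive to
    non-normality; used here to compare spreads of elongation angles.
    """
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfn, dfd = len(a) - 1, len(b) - 1
    if vb == 0:
        return FTestResult(float("inf") if va > 0 else float("nan"), (dfn, dfd),
                           float("nan"), defined=False)
    f = va / vb
    dist = sps.f(dfn, dfd)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return FTestResult(float(f), (dfn, dfd), float(p))


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Two-sidedness by the probability-mass rule: the p-value sums the
    hypergeometric probabilities of every table with the same margins
    whose probability does not exceed the observed table's. A table with a
    zero margin carries no information; p = 1 by convention, flagged.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t.sum() == 0:
        raise ValueError("table must have a positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(1.0, zero_margin=True)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return FisherResult(float(p))


def boxplot_summary(values) -> BoxplotSummary:
    """ggplot2-style five-number box summary with outliers.

    Hinges are the first/third quartiles under type-7 linear interpolation;
    whiskers reach the most extreme attained data values within
    hinge ± 1.5 * IQR (never an interpolated bound); points beyond the
    whiskers are outliers.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # type-7 by default
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    lower_whisker = float(inside.min())
    upper_whisker = float(inside.max())
    outliers = tuple(sorted(v[(v < lower_whisker) | (v > upper_whisker)]))
    return BoxplotSummary(
        float(med), float(q1), float(q3), lower_whisker, upper_whisker, outliers
    )


def contingency_fraction(in_stalk: int, total_scored: int) -> float:
    """Percentage of scored cells in one outcome class, to one decimal.

    Conventional (half-up) rounding, e.g. 10 of 23 -> 43.5 and
    32 of 41 -> 78.0.
    """
    if total_scored <= 0:
        raise ValueError("total_scored must be positive")
    if not (0 <= in_stalk <= total_scored):
        raise ValueError("require 0 <= in_stalk <= total_scored")
    pct = Decimal(100 * in_stalk) / Decimal(total_scored)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def normalize_penetrance(treated_pct: float, control_pct: float) -> float:
    """Phenotype penetrance normalized to a vehicle control, in percent:
    100 * treated / control (100 = unchanged, >100 = exacerbated)."""
    if control_pct <= 0:
        raise ValueError("control percentage must be positive")
    if treated_pct < 0:
        raise ValueError("treated percentage must be nonnegative")
    return 100.0 * treated_pct / control_pct
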