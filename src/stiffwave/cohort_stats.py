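"""Cohort-level statistical validation of the MEC_K -> ROC_BP relationship.

Covers the study's analysis chain: Pearson correlation between MEC_K and
ROC_BP over in-range subjects, the first-order regression line, iterative
two-sided Smirnov-Grubbs screening of prediction residuals, an
ANCOVA-style test of parallel regression lines between two groups (or two
studies), Bland-Altman agreement of externally predicted vs measured
ROC_BP, and the noncentral-F power computation behind the required sample
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st

from .mec_detection import OUT_OF_RANGE


@dataclass
class SubjectRecord:
    """Per-subject observables: threshold current and incision BP response."""

    subject_id: str
    meck_ma: int | str            # mA, or OUT_OF_RANGE ("OOR")
    rocbp_pct: float | None = None
    group: str | None = None

    @property
    def in_range(self) -> bool:
        return self.meck_ma != OUT_OF_RANGE


@dataclass
class BlandAltman:
    bias: float        # mean of (predicted - measured), %
    sd: float          # sample SD of differences, %
    loa_low: float     # bias - 1.96*sd
    loa_high: float    # bias + 1.96*sd
    precision: float   # 1.96*sd, half-width of the limits of agreement


@dataclass
class PowerSpec:
    """Inputs to the regression-F power/sample-size computation."""

    r2_assumed: float
    alpha: float = 0.05
    power: float = 0.8
    n_min_floor: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_assumed < 1.0:
            raise ValueError("r2_assumed must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.n_min_floor < 4:
            raise ValueError("n_min_floor must be >= 4")

    @property
    def f2(self) -> float:
        """Cohen's effect size f^2 = R^2 / (1 - R^2)."""
        return self.r2_assumed / (1.0 - self.r2_assumed)


@dataclass
class CohortStatsResult:
    n_analyzed: int
    n_out_of_range: int
    r: float
    p_r: float
    slope: float
    intercept: float
    residual_sd: float
    predictions: np.ndarray
    grubbs_outliers: list[str]
    p_parallel_slope: float | None = None
    p_parallel_intercept: float | None = None
    bland_altman: BlandAltman | None = None
    group_r: dict[str, tuple[float, float]] = field(default_factory=dict)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fit_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, np.ndarray, float]:
    """Ordinary least squares y = slope*x + intercept.

    Returns (slope, intercept, predictions, residual_sd) where residual_sd
    is the root mean squared residual with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = st.linregress(x, y)
    pred = res.slope * x + res.intercept
    resid_sd = float(np.sqrt(np.sum((y - pred) ** 2) / (x.size - 2)))
    return float(res.slope), float(res.intercept), pred, resid_sd


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = st.t.isf(alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(
    values: Sequence[float], alpha: float = 0.05, iterative: bool = True
) -> list[int]:
    """Indices of two-sided Smirnov-Grubbs outliers at level ``alpha``.

    Flags the single most extreme deviation from the mean when
    G = max|d_i - mean| / sd exceeds the critical value; if ``iterative``,
    the flagged point is removed and the test repeated until no point is
    flagged or fewer than 3 remain.
    """
    d = np.asarray(values, dtype=float)
    if d.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    remaining = list(range(d.size))
    flagged: list[int] = []
    while len(remaining) >= 3:
        sub = d[remaining]
        s = sub.std(ddof=1)
        if s == 0.0:
            warnings.warn("zero sample SD: no outliers can be flagged")
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        if dev[j] / s > grubbs_critical_value(len(remaining), alpha):
            flagged.append(remaining.pop(j))
            if not iterative:
                break
        else:
            break
    return sorted(flagged)


def parallel_lines_test(
    x1: Sequence[float], y1: Sequence[float],
    x2: Sequence[float], y2: Sequence[float],
) -> tuple[float, float]:
    """ANCOVA-style comparison of two regression lines.

    Fits the pooled model y = b0 + b1*x + b2*g + b3*(x*g) with group
    indicator g and returns the two-sided p-value of the interaction term
    (slope equality); then refits without the interaction and returns the
    two-sided p-value of the group main effect (intercept equality given a
    common slope).  The second p-value is meaningful when the first does
    not reject, mirroring the usual reporting order.
    """
    x1 = np.asarray(x1, float); y1 = np.asarray(y1, float)
    x2 = np.asarray(x2, float); y2 = np.asarray(y2, float)
    if x1.size != y1.size or x2.size != y2.size:
        raise ValueError("x and y must have equal length within each group")
    if min(x1.size, x2.size) < 3 or np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("each group needs n >= 3 with non-constant x")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])

    def _t_pvalue(X: np.ndarray, col: int) -> tuple[float, float]:
        n, p = X.shape
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < p or n <= p:
            raise ValueError("degenerate design")
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        se = np.sqrt(sigma2 * np.linalg.inv(XtX)[col, col])
        if se == 0.0:
            return float(beta[col]), 1.0 if beta[col] == 0 else 0.0
        tstat = beta[col] / se
        return float(beta[col]), float(2.0 * st.t.sf(abs(tstat), n - p))

    ones = np.ones_like(x)
    _, p_slope = _t_pvalue(np.column_stack([ones, x, g, x * g]), 3)
    _, p_intercept = _t_pvalue(np.column_stack([ones, x, g]), 2)
    return p_slope, p_intercept


def bland_altman(
    predicted: Sequence[float], measured: Sequence[float]
) -> BlandAltman:
    """Bland-Altman agreement of predicted vs measured values.

    Differences are predicted - measured; bias is their mean, the limits
    of agreement are bias +/- 1.96*SD, and "precision" is 1.96*SD (the
    half-width of the limits of agreement).
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size != m.size:
        raise ValueError("predicted and measured must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 pairs")
    d = p - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, 1.96 * sd)


def regression_f_power(n: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the slope F-test in simple linear regression.

    Numerator df 1, denominator df n-2, noncentrality lambda = n*f2.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    crit = st.f.isf(alpha, 1, n - 2)
    return float(st.ncf.sf(crit, 1, n - 2, n * f2))


def correlation_test_power(n: int, r: float, alpha: float = 0.05) -> float:
    """Approximate power of the two-sided test of a Pearson correlation.

    Noncentral-t approximation with delta = r*sqrt(n)/sqrt(1-r^2); the
    alternative mode to the fixed-design regression-F model.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    delta = r * np.sqrt(n) / np.sqrt(1.0 - r * r)
    crit = st.t.isf(alpha / 2.0, n - 2)
    return float(st.nct.sf(crit, n - 2, delta) + st.nct.cdf(-crit, n - 2, delta))


def required_sample_size(
    spec: PowerSpec, method: str = "regression_f", n_max: int = 10**6
) -> int:
    """Smallest n whose slope test reaches the requested power.

    The default ``regression_f`` mode matches G*Power's linear-regression
    F-test: power from the noncentral F with df (1, n-2) and
    noncentrality n*f^2, f^2 = R^2/(1-R^2).  ``correlation`` uses the
    noncentral-t approximation for the exact bivariate-normal correlation
    test with r = sqrt(R^2).
    """
    if method not in ("regression_f", "correlation"):
        raise ValueError("method must be 'regression_f' or 'correlation'")
    for n in range(max(spec.n_min_floor, 4), n_max + 1):
        if method == "regression_f":
            p = regression_f_power(n, spec.f2, spec.alpha)
        else:
            p = correlation_test_power(n, np.sqrt(spec.r2_assumed), spec.alpha)
        if p >= spec.power:
            return n
    raise ValueError(f"requested power unreachable within n <= {n_max}")


def run_cohort_analysis(
    subjects: Sequence[SubjectRecord],
    external_equation: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> CohortStatsResult:
    """Full statistical validation of a cohort.

    Excludes OUT_OF_RANGE subjects, computes the Pearson correlation and
    regression line of ROC_BP on MEC_K, screens the (predicted - measured)
    residuals with the iterative Grubbs test, and, when requested or
    possible, the Bland-Altman agreement against an external prediction
    equation and the parallel-lines comparison between two groups.
    """
    in_range = [s for s in subjects
                if s.in_range and s.rocbp_pct is not None
                and np.isfinite(s.rocbp_pct)]
    n_oor = len(subjects) - len(in_range)
    if len(in_range) < 3:
        raise ValueError("need at least 3 in-range subjects")
    x = np.array([float(s.meck_ma) for s in in_range])
    y = np.array([float(s.rocbp_pct) for s in in_range])

    r, p_r = pearson(x, y)
    slope, intercept, pred, resid_sd = fit_regression(x, y)
    out_idx = grubbs_outliers(pred - y, alpha=alpha)
    outlier_ids = [in_range[i].subject_id for i in out_idx]

    ba = None
    if external_equation is not None:
        ext_slope, ext_intercept = external_equation
        ba = bland_altman(ext_slope * x + ext_intercept, y)

    p_par_slope = p_par_intercept = None
    group_r: dict[str, tuple[float, float]] = {}
    labels = sorted({s.group for s in in_range if s.group is not None})
    if len(labels) == 2:
        ga = [s for s in in_range if s.group == labels[0]]
        gb = [s for s in in_range if s.group == labels[1]]
        if min(len(ga), len(gb)) >= 3:
            xa = np.array([float(s.meck_ma) for s in ga])
            ya = np.array([float(s.rocbp_pct) for s in ga])
            xb = np.array([float(s.meck_ma) for s in gb])
            yb = np.array([float(s.rocbp_pct) for s in gb])
            p_par_slope, p_par_intercept = parallel_lines_test(xa, ya, xb, yb)
            group_r[labels[0]] = pearson(xa, ya)
            group_r[labels[1]] = pearson(xb, yb)

    return CohortStatsResult(
        n_analyzed=len(in_range),
        n_out_of_range=n_oor,
        r=r, p_r=p_r,
        slope=slope, intercept=intercept, residual_sd=resid_sd,
        predictions=pred,
        grubbs_outliers=outlier_ids,
        p_parallel_slope=p_par_slope,
        p_parallel_intercept=p_par_intercept,
        bland_altman=ba,
        group_r=group_r,
    )
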