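"""Method-comparison statistics: paired tests, identity regression, Bland-Altman
limits of agreement, trend analysis, and correlation power.

Conventions (documented in every emitted report):

* differences are method A minus method B, with A = DXA and B = the 4C
  criterion throughout the pipeline;
* identity regression puts the criterion on the y-axis (criterion ~ predictor)
  and tests the slope against 1 and the intercept against 0;
* SDs use the n-1 denominator, the SEE uses n-2, limits of agreement use a
  1.96 multiplier by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BlandAltman",
    "RegressionVsIdentity",
    "AgreementReport",
    "paired_comparison",
    "one_sample_vs_reference",
    "identity_regression",
    "r_squared_percent",
    "bland_altman",
    "moment_loa",
    "detectable_correlation",
    "correlate_differences",
    "agreement_report",
]

log = logging.getLogger(__name__)


def _as_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1-d vectors of length >= 3")
    return x, y


def paired_comparison(
    x, y, normality_alpha: float = 0.05
) -> tuple[float, float, str]:
    """Paired two-sample comparison with a normality gate on the differences.

    Shapiro-Wilk at ``normality_alpha`` decides between the paired t-test and
    the Wilcoxon signed-rank test; returns (statistic, p, test_name) and logs
    the branch taken.
    """
    x, y = _as_vectors(x, y)
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            # identical vectors: t-test convention t=0, p=1
            return 0.0, 1.0, "paired_t"
        raise ValueError("paired differences have zero variance; test degenerate")
    sw_p = stats.shapiro(d).pvalue
    if sw_p >= normality_alpha:
        res = stats.ttest_rel(x, y)
        log.debug("paired_comparison: Shapiro p=%.3f -> paired t", sw_p)
        return float(res.statistic), float(res.pvalue), "paired_t"
    res = stats.wilcoxon(x, y)
    log.debug("paired_comparison: Shapiro p=%.3f -> Wilcoxon", sw_p)
    return float(res.statistic), float(res.pvalue), "wilcoxon"


def one_sample_vs_reference(x, ref: float) -> tuple[float, float]:
    """One-sample t-test of mean(x) against a reference constant."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d vector of length >= 3")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; one-sample t undefined")
    res = stats.ttest_1samp(x, ref)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RegressionVsIdentity:
    """OLS of criterion on predictor with tests against the line of identity."""

    slope: float
    intercept: float
    r: float
    see: float
    slope_p_vs_1: float
    intercept_p_vs_0: float
    n: int


def identity_regression(criterion, predictor) -> RegressionVsIdentity:
    """Regress the criterion method on the predictor and test slope=1, intercept=0.

    SEE = sqrt(SSE / (n-2)).  With an exact fit the standard errors collapse
    to zero; the slope/intercept p-values are then reported as 0 when the
    estimate differs from the null value and 1 when it equals it.
    """
    y, x = _as_vectors(criterion, predictor)
    n = len(x)
    if np.std(x, ddof=1) == 0:
        raise ValueError("predictor variance is zero")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    see = math.sqrt(sse / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_slope = see / math.sqrt(sxx) if sxx > 0 else float("nan")
    se_intercept = see * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)

    def _t_p(estimate: float, null: float, se: float) -> float:
        if se == 0:
            return 1.0 if estimate == null else 0.0
        t = (estimate - null) / se
        return float(2 * stats.t.sf(abs(t), n - 2))

    return RegressionVsIdentity(
        slope=slope,
        intercept=intercept,
        r=float(res.rvalue),
        see=see,
        slope_p_vs_1=_t_p(slope, 1.0, se_slope),
        intercept_p_vs_0=_t_p(intercept, 0.0, se_intercept),
        n=n,
    )


def r_squared_percent(r: float) -> int:
    """Variance explained, as a whole-number percentage: round(100*r^2)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    return int(round(100.0 * r * r))


@dataclass(frozen=True)
class BlandAltman:
    """Bias, 95% limits of agreement and proportional-bias trend for one pair."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    trend_r: float
    trend_p: float
    trend_computable: bool


def bland_altman(method_a, method_b, loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement of method A against method B (diff = A - B).

    LOA = bias +/- multiplier * SD(diff) with the sample (n-1) SD.  The trend
    is the Pearson correlation of the differences against the pairwise means;
    when either has zero variance the trend is reported as not computable
    (NaN) and a zero-variance difference triggers an LOA-collapse warning.
    """
    a, b = _as_vectors(method_a, method_b)
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        log.warning("bland_altman: zero difference variance; limits collapse to the bias")
    if sd == 0 or mean.std(ddof=1) == 0:
        trend_r, trend_p, computable = float("nan"), float("nan"), False
    else:
        tr = stats.pearsonr(diff, mean)
        trend_r, trend_p, computable = float(tr.statistic), float(tr.pvalue), True
    return BlandAltman(
        n=len(a),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - loa_multiplier * sd,
        loa_upper=bias + loa_multiplier * sd,
        trend_r=trend_r,
        trend_p=trend_p,
        trend_computable=computable,
    )


def moment_loa(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    r_ab: float,
    loa_multiplier: float = 1.96,
) -> tuple[float, float, float]:
    """Closed-form limits of agreement from the two methods' moments.

    bias = mean_a - mean_b and SD(diff) = sqrt(sd_a^2 + sd_b^2 - 2 r sd_a sd_b);
    returns (bias, lower, upper).  Agrees exactly with :func:`bland_altman`
    when fed the sample moments of the same data.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("sd_a and sd_b must be positive")
    if not -1.0 <= r_ab <= 1.0:
        raise ValueError("r_ab must lie in [-1, 1]")
    bias = mean_a - mean_b
    var_diff = sd_a**2 + sd_b**2 - 2.0 * r_ab * sd_a * sd_b
    sd_diff = math.sqrt(max(var_diff, 0.0))
    return bias, bias - loa_multiplier * sd_diff, bias + loa_multiplier * sd_diff


def detectable_correlation(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    bias_correction: bool = True,
) -> float:
    """Smallest |r| detectable two-sided at the given alpha and power, n subjects.

    Uses the Fisher z approximation: atanh(r)*sqrt(n-3) = z_{1-alpha/2} + z_power.
    With ``bias_correction`` (default) the small-sample mean of the z transform,
    atanh(rho) + rho/(2(n-1)), is used instead of atanh(rho) alone — the form
    standard power software applies.  At n=27, alpha=0.05, power=0.80 this
    yields 0.51 (two decimals).
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    target = (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) / math.sqrt(n - 3)

    def f(r: float) -> float:
        z = math.atanh(r)
        if bias_correction:
            z += r / (2 * (n - 1))
        return z - target

    if f(1 - 1e-12) < 0:
        raise ValueError("no detectable correlation below 1 for these parameters")
    return float(optimize.brentq(f, 1e-12, 1 - 1e-12, xtol=1e-12))


def correlate_differences(diffs, covariate) -> tuple[float, float]:
    """Pearson correlation of method differences against a covariate.

    Returns (r, p); (nan, nan) when either input has zero variance.
    """
    d, c = _as_vectors(diffs, covariate)
    if d.std(ddof=1) == 0 or c.std(ddof=1) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(d, c)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one variable pair (A = DXA, B = 4C criterion)."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    trend_r: float
    trend_p: float
    slope: float
    intercept: float
    r: float
    see: float
    slope_p_vs_1: float
    intercept_p_vs_0: float
    mean_comparison_stat: float
    mean_comparison_p: float
    test_used: str

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(
    method_a, method_b, loa_multiplier: float = 1.96, normality_alpha: float = 0.05
) -> AgreementReport:
    """All agreement statistics for A (DXA) vs B (criterion) in one pass.

    Combines the paired mean comparison, the criterion-on-predictor identity
    regression (B on A) and the Bland-Altman analysis (diff = A - B).
    """
    a, b = _as_vectors(method_a, method_b)
    ba = bland_altman(a, b, loa_multiplier=loa_multiplier)
    try:
        stat, p, test = paired_comparison(a, b, normality_alpha=normality_alpha)
    except ValueError:
        stat, p, test = float("nan"), float("nan"), "degenerate"
    if np.std(a, ddof=1) > 0:
        reg = identity_regression(b, a)
        slope, intercept, r, see = reg.slope, reg.intercept, reg.r, reg.see
        sp, ip = reg.slope_p_vs_1, reg.intercept_p_vs_0
    else:
        slope = intercept = r = see = sp = ip = float("nan")
    return AgreementReport(
        n=ba.n,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        trend_r=ba.trend_r,
        trend_p=ba.trend_p,
        slope=slope,
        intercept=intercept,
        r=r,
        see=see,
        slope_p_vs_1=sp,
        intercept_p_vs_0=ip,
        mean_comparison_stat=stat,
        mean_comparison_p=p,
        test_used=test,
    )
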