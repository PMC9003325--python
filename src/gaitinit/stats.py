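"""Method-comparison and group-comparison statistics.

Agreement between the wearable and the gold-standard system is quantified
with Bland–Altman statistics (bias, coefficient of variation, 95 % limits
of agreement), the single-measure absolute-agreement intraclass correlation
ICC(A,1) from the two-way ANOVA decomposition (with Cronbach's alpha and
the Fleiss reliability classification), signed and absolute mean event
errors, and Pearson correlation/regression of one system on the other.

Group contrasts use Shapiro–Wilk-gated unpaired t-tests with Cohen's d
(pooled SD) and the conventional effect-size classes; correlations with
external scores use Pearson or Spearman coefficients with a five-band
magnitude classification.

Throughout, paired differences are taken in the fixed order IMU minus
force platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats as sst

from .errors import UsageError
from .gi_metrics import METRIC_NAMES, GIMetrics

Z_LOA = 1.96  # normal quantile defining the 95 % limits of agreement


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_half_width: float
    cv_percent: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "bias", "sd_diff", "loa_low", "loa_high",
                 "loa_half_width", "cv_percent")}


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements (differences x − y;
    by convention x is the wearable system, y the force platform).

    The SD of differences uses the n−1 denominator; the coefficient of
    variation is 100 × SD of differences / mean of the pairwise means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise UsageError("need at least 3 pairs for Bland-Altman analysis")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean_of_means = float(((x + y) / 2).mean())
    cv = 100.0 * sd / mean_of_means if mean_of_means != 0 else np.inf
    return BlandAltmanResult(
        n=len(x), bias=bias, sd_diff=sd,
        loa_low=bias - Z_LOA * sd, loa_high=bias + Z_LOA * sd,
        loa_half_width=Z_LOA * sd, cv_percent=cv)


# ---------------------------------------------------------------------------
# ICC(A,1) and Cronbach's alpha
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    cronbach_alpha: float
    fleiss_class: str
    flagged: bool = False   # zero between-subject variance -> undefined

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("icc", "ci_low", "ci_high", "cronbach_alpha",
                 "fleiss_class", "flagged")}


def classify_icc(icc: float) -> str:
    """Fleiss reliability class: poor below 0.40, fair to good from 0.40 to
    0.75 inclusive, excellent above 0.75."""
    if not -1.0 <= icc <= 1.0:
        raise UsageError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.40:
        return "poor"
    if icc <= 0.75:
        return "fair-to-good"
    return "excellent"


def icc_two_way_absolute(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC(A,1) of an n-subjects × k-raters
    table, from the two-way ANOVA mean squares, with the F-based 95 %
    confidence interval and Cronbach's alpha from the same decomposition.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise UsageError("ratings must be a 2-D table with >= 2 raters")
    n, k = x.shape
    if n < 5:
        raise UsageError("need at least 5 subjects for the ICC")
    if np.any(~np.isfinite(x)):
        raise UsageError("ratings must contain no missing values")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30 or msr < 1e-30:
        return ICCResult(np.nan, np.nan, np.nan, np.nan, "undefined",
                         flagged=True)
    icc = (msr - mse) / denom
    cronbach = 1.0 - mse / msr  # == consistency-type average-measure ICC

    # F-based confidence bounds (two-way, absolute agreement, single measure)
    if mse < 1e-30 and msc < 1e-30:
        lo, hi = icc, icc       # perfect agreement: CI collapses
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a):
            lo, hi = 1.0, 1.0
        else:
            # Satterthwaite degrees of freedom for the F-based bounds
            v = ((a * msc + b * mse) ** 2 /
                 ((a * msc) ** 2 / (k - 1.0) +
                  (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))))
            f1 = float(sst.f.ppf(1 - alpha / 2, n - 1.0, v))
            f2 = float(sst.f.ppf(1 - alpha / 2, v, n - 1.0))
            lo = (n * (msr - f1 * mse) /
                  (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f2 * msr - mse) /
                  (k * msc + (k * n - k - n) * mse + n * f2 * msr))
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    return ICCResult(icc=float(icc), ci_low=min(lo, float(icc)),
                     ci_high=max(hi, float(icc)),
                     cronbach_alpha=float(cronbach),
                     fleiss_class=classify_icc(float(np.clip(icc, -1, 1))))


# ---------------------------------------------------------------------------
# mean event errors
# ---------------------------------------------------------------------------

def mean_errors(instants_a: np.ndarray, instants_b: np.ndarray
                ) -> tuple[float, float]:
    """Signed mean error and true mean absolute error of paired event times
    (a − b). Both are reported because published "MAE" summaries sometimes
    carry signs, i.e. are signed means; labelling both avoids the ambiguity.
    """
    a = np.asarray(instants_a, dtype=float)
    b = np.asarray(instants_b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("paired instants must have equal length")
    d = a - b
    return float(d.mean()), float(np.abs(d).mean())


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_stat: float
    p_value: float
    cohen_d: float
    d_class: str
    normality_ok_a: bool
    normality_ok_b: bool
    flagged: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def classify_cohen_d(d: float) -> str:
    ad = abs(d)
    if ad < 0.20:
        return "negligible"
    if ad < 0.50:
        return "small"
    if ad < 0.80:
        return "moderate"
    return "large"


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference with the classical pooled SD
    (degrees-of-freedom weights)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / pooled)


def group_compare(a: np.ndarray, b: np.ndarray,
                  normality_alpha: float = 0.05) -> GroupComparisonResult:
    """Two-sided unpaired t-test between two groups with Shapiro–Wilk
    normality gates (reported as flags; the test statistic is computed
    regardless) and Cohen's d with its magnitude class."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise UsageError("need at least 3 observations per group")
    norm_a = bool(sst.shapiro(a).pvalue > normality_alpha) if a.std() > 0 else False
    norm_b = bool(sst.shapiro(b).pvalue > normality_alpha) if b.std() > 0 else False
    flagged = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if flagged:
        t_stat, p = np.nan, np.nan
        d = 0.0 if a.mean() == b.mean() else np.nan
    else:
        t_stat, p = sst.ttest_ind(a, b, equal_var=True)
        d = cohen_d(a, b)
    return GroupComparisonResult(
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t_stat=float(t_stat), p_value=float(p), cohen_d=float(d),
        d_class=classify_cohen_d(d) if np.isfinite(d) else "undefined",
        normality_ok_a=norm_a, normality_ok_b=norm_b, flagged=flagged)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    magnitude_class: str
    n: int
    flagged: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def classify_correlation(r: float) -> str:
    """Five-band magnitude class of |r|; boundaries belong to the higher
    band (0.20 is slight, 0.40 moderate, 0.60 strong, 0.80 very strong)."""
    ar = abs(r)
    if ar < 0.20:
        return "very slight"
    if ar < 0.40:
        return "slight"
    if ar < 0.60:
        return "moderate"
    if ar < 0.80:
        return "strong"
    return "very strong"


def correlate(x: np.ndarray, y: np.ndarray,
              method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p-value and the
    five-band magnitude class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 5:
        raise UsageError("need >= 5 pairs of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, np.nan, np.nan, "undefined",
                                 n=len(x), flagged=True)
    if method == "pearson":
        r, p = sst.pearsonr(x, y)
    elif method == "spearman":
        r, p = sst.spearmanr(x, y)
    else:
        raise UsageError(f"method must be pearson|spearman, got {method!r}")
    return CorrelationResult(method, float(r), float(p),
                             classify_correlation(float(r)), n=len(x))


# ---------------------------------------------------------------------------
# Bland–Altman sample size
# ---------------------------------------------------------------------------

def _ba_power(n: int, bias: float, sd: float, delta: float,
              alpha: float) -> float:
    """Exact probability that both 95 % LOA confidence bounds lie inside
    ±delta, for a sample of n normal differences N(bias, sd²).

    The sample mean and SD are independent; conditioning on the SD, the
    containment event is an interval in the sample mean, integrated over the
    chi distribution of the SD.
    """
    df = n - 1
    tq = sst.t.ppf(1 - alpha / 2, df)
    se_factor = np.sqrt(1.0 / n + Z_LOA ** 2 / (2.0 * df))

    def integrand(u: float) -> float:
        # u ~ chi2(df); s = sd * sqrt(u / df)
        s = sd * np.sqrt(u / df)
        margin = Z_LOA * s + tq * se_factor * s
        lo = -delta + margin
        hi = delta - margin
        if hi <= lo:
            return 0.0
        scale = sd / np.sqrt(n)
        p = (sst.norm.cdf((hi - bias) / scale)
             - sst.norm.cdf((lo - bias) / scale))
        return p * sst.chi2.pdf(u, df)

    power, _ = integrate.quad(integrand, 0, sst.chi2.ppf(1 - 1e-10, df),
                              limit=200)
    return float(power)


def ba_sample_size(expected_bias: float, expected_sd: float,
                   max_allowed_diff: float, alpha: float = 0.05,
                   power: float = 0.9, n_max: int = 2000) -> int:
    """Minimum number of paired differences such that, with the requested
    power, both 95 % limits-of-agreement confidence bounds fall within
    ±``max_allowed_diff``. Computed by exact-power iteration over n.
    """
    if max_allowed_diff <= abs(expected_bias) + Z_LOA * expected_sd:
        raise UsageError(
            "max_allowed_diff must exceed |bias| + 1.96*sd, otherwise the "
            "limits of agreement themselves violate the bound")
    if expected_sd <= 0:
        return 3
    for n in range(3, n_max + 1):
        if _ba_power(n, expected_bias, expected_sd, max_allowed_diff,
                     alpha) >= power:
            return n
    raise UsageError(f"required sample size exceeds {n_max}")


# ---------------------------------------------------------------------------
# cross-metric agreement report
# ---------------------------------------------------------------------------

@dataclass
class MetricAgreement:
    bland_altman: BlandAltmanResult
    icc: ICCResult
    pearson: CorrelationResult
    slope: float
    intercept: float
    signed_mean_error: float
    mean_absolute_error: float

    def as_dict(self) -> dict:
        return {"bland_altman": self.bland_altman.as_dict(),
                "icc": self.icc.as_dict(),
                "pearson": self.pearson.as_dict(),
                "slope": self.slope, "intercept": self.intercept,
                "signed_mean_error": self.signed_mean_error,
                "mean_absolute_error": self.mean_absolute_error}


@dataclass
class AgreementReport:
    """Per-metric agreement of the wearable against the gold standard plus
    cross-metric mean(SD) summaries in the style LOA 0.04(0.01) s,
    r 0.99(0.01)."""

    n_subjects: int
    per_metric: dict[str, MetricAgreement]
    summary: dict[str, dict[str, float]]

    def as_dict(self) -> dict:
        return {"n_subjects": self.n_subjects,
                "per_metric": {m: r.as_dict() for m, r in self.per_metric.items()},
                "summary": self.summary}


def _metrics_table(metrics: list[GIMetrics]) -> dict[str, dict[str, float]]:
    return {m.subject_id: m.as_dict() for m in metrics}


def agreement_report(metrics_imu: list[GIMetrics],
                     metrics_fp: list[GIMetrics]) -> AgreementReport:
    """Full agreement analysis of subject-averaged metrics from the two
    systems: Bland–Altman, ICC(A,1), Pearson r and the regression slope of
    the wearable on the gold standard, for each of the five metrics, plus
    cross-metric mean(SD) summaries of LOA half-width, CV, r and slope."""
    tab_imu = _metrics_table(metrics_imu)
    tab_fp = _metrics_table(metrics_fp)
    subjects = sorted(set(tab_imu) & set(tab_fp))
    if len(subjects) < 5:
        raise UsageError(f"only {len(subjects)} matched subjects (< 5)")
    per_metric: dict[str, MetricAgreement] = {}
    for name in METRIC_NAMES:
        x = np.array([tab_imu[s][name] for s in subjects])
        y = np.array([tab_fp[s][name] for s in subjects])
        ba = bland_altman(x, y)
        icc = icc_two_way_absolute(np.column_stack([x, y]))
        pear = correlate(x, y, "pearson")
        if np.ptp(y) > 0:            # wearable regressed on gold standard
            reg = sst.linregress(y, x)
            slope, intercept = float(reg.slope), float(reg.intercept)
        else:                        # degenerate: no between-subject spread
            slope, intercept = np.nan, np.nan
        me, mae = mean_errors(x, y)
        per_metric[name] = MetricAgreement(
            bland_altman=ba, icc=icc, pearson=pear,
            slope=slope, intercept=intercept,
            signed_mean_error=me, mean_absolute_error=mae)

    def _ms(values):
        v = np.asarray(values, dtype=float)
        return {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}

    summary = {
        "loa_half_width_s": _ms([m.bland_altman.loa_half_width
                                 for m in per_metric.values()]),
        "cv_percent": _ms([m.bland_altman.cv_percent
                           for m in per_metric.values()]),
        "pearson_r": _ms([m.pearson.r for m in per_metric.values()]),
        "slope": _ms([m.slope for m in per_metric.values()]),
    }
    return AgreementReport(n_subjects=len(subjects), per_metric=per_metric,
                           summary=summary)
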