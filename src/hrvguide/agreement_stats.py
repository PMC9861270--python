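"""Method-agreement and reliability statistics for paired HRV measurements.

Implements the validation battery used in device-comparison studies:

* a Shapiro–Wilk normality gate for small samples,
* paired mean-difference tests with Bonferroni scaling,
* Cohen's d on paired differences with interpretation bands,
* Pearson correlation with interpretation bands,
* ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — with an F-based confidence interval at a configurable
  level (reliability tables conventionally print a 90% CI),
* SEM (absolute and as % of the group mean) and the minimal detectable
  change MDC = 1.96 × SEM × √2,
* Bland–Altman bias and 95% limits of agreement.

Band thresholds follow the conventional printed cut-offs; each band is a
half-open interval anchored at its printed lower edge, applied to the
magnitude of the statistic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

__all__ = [
    "PairedSample",
    "AgreementReport",
    "ReliabilityReport",
    "BlandAltmanResult",
    "PearsonResult",
    "MDC_FACTOR",
    "shapiro_wilk_gate",
    "interpret_cohens_d",
    "interpret_pearson_r",
    "interpret_icc",
    "paired_comparison",
    "pearson_with_band",
    "icc_reliability",
    "sem_and_mdc",
    "mdc_from_sem_percent",
    "bland_altman",
    "compare",
    "reliability",
]

#: MDC / SEM ratio: 1.96 * sqrt(2).
MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class PairedSample:
    """Two aligned measurement vectors (one value per subject)."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple = ("A", "B")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValidationError("paired sample requires two equal-length 1-D vectors")
        if x.size < 3:
            raise InsufficientDataError("paired sample requires n >= 3 subjects")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def diffs(self) -> np.ndarray:
        return self.x - self.y

    def swapped(self) -> "PairedSample":
        return PairedSample(self.y, self.x, (self.labels[1], self.labels[0]))


@dataclass
class AgreementReport:
    """Paired-comparison statistics between two measurement conditions."""

    labels: tuple
    n: int
    mean_diff: float
    p_value: float
    cohens_d: float
    d_interpretation: str
    effect_ci: tuple  # 95% CI of the mean difference
    cohens_d_ci: tuple  # approximate 95% CI of d itself (labelled as such)
    pearson_r: Optional[float] = None
    r_interpretation: Optional[str] = None
    bias: Optional[float] = None
    loa_lower: Optional[float] = None
    loa_upper: Optional[float] = None
    warnings: tuple = ()


@dataclass
class ReliabilityReport:
    """Trial-to-trial reliability of one measurement condition."""

    n: int
    trial_mean_diff: tuple  # (mean, SD) of trial1 - trial2
    icc: float
    icc_ci: tuple
    icc_interpretation: str
    ci_level: float
    sem_abs: float
    sem_percent: float
    mdc_abs: float
    group_mean: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement with the per-subject pairs."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    interpretation: str
    p_value: float


def shapiro_wilk_gate(values: Sequence[float], alpha: float = 0.05):
    """Shapiro–Wilk normality test for small samples (3 <= n < 50).

    Returns ``(normal, W, p)`` where ``normal`` is True when normality is
    NOT rejected at ``alpha``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size >= 50:
        raise ValidationError(
            f"Shapiro–Wilk gate is defined for 3 <= n < 50, got n={arr.size}"
        )
    w, p = stats.shapiro(arr)
    return bool(p > alpha), float(w), float(p)


def interpret_cohens_d(d: float) -> str:
    """Band an effect size by magnitude: trivial/small/moderate/large."""
    m = abs(d)
    if m < 0.20:
        return "trivial"
    if m < 0.50:
        return "small"
    if m < 0.80:
        return "moderate"
    return "large"


def interpret_pearson_r(r: float) -> str:
    """Band a correlation magnitude (trivial ... almost_perfect)."""
    m = abs(r)
    if m < 0.10:
        return "trivial"
    if m < 0.30:
        return "small"
    if m < 0.50:
        return "moderate"
    if m < 0.70:
        return "high"
    if m < 0.90:
        return "very_high"
    return "almost_perfect"


def interpret_icc(icc: float) -> str:
    """Band an ICC: poor_to_moderate / good / excellent."""
    if icc < 0.75:
        return "poor_to_moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def paired_comparison(sample: PairedSample, n_comparisons: int = 1) -> AgreementReport:
    """Paired mean-difference test with Bonferroni scaling and effect size.

    ``mean_diff = mean(x) - mean(y)``; the paired-t p value is multiplied
    by ``n_comparisons`` (the size of the comparison family) and capped at
    1.0.  Cohen's d is computed on the paired differences
    (``mean_diff / SD(x - y)``, often written d_z); ``effect_ci`` is the
    95% CI of the mean difference and ``cohens_d_ci`` an approximate
    normal-theory 95% CI of d itself.
    """
    if n_comparisons < 1:
        raise ValidationError("n_comparisons must be >= 1")
    d = sample.diffs
    n = sample.n
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    warns: list[str] = []

    if sd_diff == 0.0:
        if mean_diff == 0.0:
            p, cohens_d = 1.0, 0.0
        else:
            p, cohens_d = 0.0, math.copysign(math.inf, mean_diff)
            warns.append("zero variance of differences: Cohen's d reported as infinite")
        ci = (mean_diff, mean_diff)
        d_ci = (cohens_d, cohens_d)
    else:
        t_stat, p_raw = stats.ttest_rel(sample.x, sample.y)
        p = min(1.0, float(p_raw) * n_comparisons)
        cohens_d = mean_diff / sd_diff
        t_crit = stats.t.ppf(0.975, n - 1)
        half = t_crit * sd_diff / math.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
        se_d = math.sqrt(1.0 / n + cohens_d**2 / (2.0 * n))
        d_ci = (cohens_d - 1.96 * se_d, cohens_d + 1.96 * se_d)

    return AgreementReport(
        labels=sample.labels,
        n=n,
        mean_diff=mean_diff,
        p_value=p,
        cohens_d=cohens_d,
        d_interpretation=interpret_cohens_d(cohens_d),
        effect_ci=ci,
        cohens_d_ci=d_ci,
        warnings=tuple(warns),
    )


def pearson_with_band(sample: PairedSample) -> PearsonResult:
    """Product-moment correlation with its interpretation band.

    The band is applied to |r|; the sign is carried by ``r`` itself.
    """
    if sample.x.std() == 0 or sample.y.std() == 0:
        raise UndefinedStatisticError("Pearson r is undefined for a constant vector")
    r, p = stats.pearsonr(sample.x, sample.y)
    return PearsonResult(r=float(r), interpretation=interpret_pearson_r(r), p_value=float(p))


def _icc_mean_squares(data: np.ndarray):
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(0.0, ss_total - ss_rows - ss_cols)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_reliability(
    trial1: Sequence[float],
    trial2: Sequence[float],
    ci_level: float = 0.90,
) -> tuple[float, tuple, str]:
    """ICC(2,1) — absolute agreement, single measurement — with CI.

    The two-way random-effects model treats subjects and trials as random
    samples; the CI uses the F-quantile construction of McGraw & Wong at
    ``ci_level``.  Returns ``(icc, (lower, upper), interpretation)``; the
    point estimate and CI bounds are clipped into [0, 1].
    """
    x = np.asarray(trial1, dtype=float)
    y = np.asarray(trial2, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("trials must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise InsufficientDataError("ICC requires n >= 3 subjects")
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must be in (0, 1)")

    data = np.column_stack([x, y])
    k = 2
    msr, msc, mse = _icc_mean_squares(data)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-14 or denom <= 0:
        raise UndefinedStatisticError("ICC undefined: no between-subject variance")
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        ci = (1.0, 1.0)
        icc = 1.0
    else:
        alpha = 1.0 - ci_level
        r = min(icc, 1.0 - 1e-12)
        a = k * r / (n * (1.0 - r))
        b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        ci = (max(0.0, min(1.0, lower)), max(0.0, min(1.0, upper)))

    icc = max(0.0, min(1.0, float(icc)))
    return icc, ci, interpret_icc(icc)


def sem_and_mdc(
    trial1: Sequence[float],
    trial2: Sequence[float],
    icc: float,
    group_mean: float,
) -> tuple[float, float, float]:
    """SEM and MDC from a two-trial design and its ICC.

    ``sem_abs = pooled SD × sqrt(1 - ICC)`` with the pooled SD of the two
    trials; ``sem_percent`` anchors it to the (positive) group mean;
    ``mdc_abs = 1.96 × sem_abs × sqrt(2)``.

    Returns ``(sem_abs, sem_percent, mdc_abs)``.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValidationError("icc must lie in [0, 1]")
    if group_mean <= 0:
        raise ValidationError("group_mean must be positive")
    x = np.asarray(trial1, dtype=float)
    y = np.asarray(trial2, dtype=float)
    pooled_sd = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    sem_abs = pooled_sd * math.sqrt(1.0 - icc)
    return sem_abs, 100.0 * sem_abs / group_mean, MDC_FACTOR * sem_abs


def mdc_from_sem_percent(sem_percent: float, group_mean: float) -> tuple[float, float]:
    """Recover (sem_abs, mdc_abs) from a printed SEM% and its group mean."""
    if group_mean <= 0:
        raise ValidationError("group_mean must be positive")
    sem_abs = sem_percent / 100.0 * group_mean
    return sem_abs, MDC_FACTOR * sem_abs


def bland_altman(sample: PairedSample) -> BlandAltmanResult:
    """Bias (mean x−y) and 95% limits of agreement bias ± 1.96 SD(x−y)."""
    d = sample.diffs
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=(sample.x + sample.y) / 2.0,
        diffs=d,
    )


def compare(sample: PairedSample, n_comparisons: int = 1) -> AgreementReport:
    """Full agreement report: paired test, correlation, Bland–Altman."""
    report = paired_comparison(sample, n_comparisons)
    try:
        pr = pearson_with_band(sample)
        report.pearson_r = pr.r
        report.r_interpretation = pr.interpretation
    except UndefinedStatisticError:
        report.warnings = report.warnings + ("Pearson r undefined (constant vector)",)
    ba = bland_altman(sample)
    report.bias = ba.bias
    report.loa_lower = ba.loa_lower
    report.loa_upper = ba.loa_upper
    return report


def reliability(
    trial1: Sequence[float],
    trial2: Sequence[float],
    ci_level: float = 0.90,
    group_mean: Optional[float] = None,
) -> ReliabilityReport:
    """Full trial-retrial reliability report (ICC, SEM, MDC).

    ``group_mean`` defaults to the mean of all values across both trials;
    reliability tables in device studies anchor SEM% to the condition's
    own group mean.
    """
    x = np.asarray(trial1, dtype=float)
    y = np.asarray(trial2, dtype=float)
    icc, ci, band = icc_reliability(x, y, ci_level)
    if group_mean is None:
        group_mean = float(np.concatenate([x, y]).mean())
    sem_abs, sem_pct, mdc_abs = sem_and_mdc(x, y, icc, group_mean)
    d = x - y
    return ReliabilityReport(
        n=int(x.size),
        trial_mean_diff=(float(d.mean()), float(d.std(ddof=1))),
        icc=icc,
        icc_ci=ci,
        icc_interpretation=band,
        ci_level=ci_level,
        sem_abs=sem_abs,
        sem_percent=sem_pct,
        mdc_abs=mdc_abs,
        group_mean=group_mean,
    )
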