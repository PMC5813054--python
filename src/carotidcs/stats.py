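"""Repeatability statistics: ICC, coefficient of variation, Bland-Altman
agreement limits and the paired t-test.

Conventions follow common scan-rescan practice: the coefficient of
variation is the sample standard deviation of the paired differences
divided by the mean of the pair means, in percent; the default ICC form is
ICC(2,1) (two-way random effects, absolute agreement, single measures) with
its 95% confidence interval from the F distribution; Bland-Altman limits of
agreement are the mean difference +/- 1.96 standard deviations.  Agreement
is categorised as excellent above 0.75, good from 0.40 to 0.75 inclusive,
poor below 0.40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "RepeatabilityResult",
    "cov",
    "icc",
    "bland_altman",
    "paired_ttest",
    "classify_agreement",
    "repeatability_summary",
]


@dataclass
class PairedMeasurements:
    """Two paired measurement vectors (first and second measurement of the
    same units), e.g. scan vs rescan or reader 1 vs reader 2."""

    x1: np.ndarray
    x2: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.ndim != 1 or self.x2.ndim != 1:
            raise ValueError("x1 and x2 must be 1-D")
        if len(self.x1) != len(self.x2):
            raise ValueError("x1 and x2 must have equal length")

    @property
    def n(self) -> int:
        return len(self.x1)

    @property
    def diffs(self) -> np.ndarray:
        return self.x1 - self.x2

    @property
    def means(self) -> np.ndarray:
        return (self.x1 + self.x2) / 2.0


@dataclass
class RepeatabilityResult:
    icc: float
    icc_ci: tuple[float, float]
    cov_percent: float
    bland_altman: tuple[float, float, float]  # (mean_diff, loa_lo, loa_hi)
    ttest: tuple[float, float, int]  # (t, p, df)
    category: str
    n: int
    icc_model: str = "icc2"


def cov(pairs: PairedMeasurements) -> float:
    """Coefficient of variation in percent.

    100 x sd(x1 - x2) / mean of the pair means, with the sample (n-1)
    standard deviation.
    """
    if pairs.n < 2:
        raise ValueError("CoV needs at least 2 pairs")
    denom = float(np.mean(pairs.means))
    if denom == 0:
        raise ValueError("CoV undefined: mean of pair means is zero")
    sd = float(np.std(pairs.diffs, ddof=1))
    return 100.0 * sd / denom


def _anova_mean_squares(pairs: PairedMeasurements) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n-subjects x 2-raters table."""
    X = np.stack([pairs.x1, pairs.x2], axis=1)  # (n, k)
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc(
    pairs: PairedMeasurements,
    model: str = "icc2",
    ci_alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Intraclass correlation with its 95% confidence interval.

    ``model="icc2"`` is ICC(2,1): two-way random effects, absolute
    agreement, single measures -- the standard choice for scan-rescan
    agreement, where systematic session differences count against
    agreement.  ``model="icc3"`` (two-way mixed, consistency) is also
    available.  Confidence bounds follow the Shrout-Fleiss / McGraw-Wong
    F-distribution formulas.
    """
    if pairs.n < 3:
        raise ValueError("ICC needs at least 3 pairs for a meaningful CI")
    msr, msc, mse, n, k = _anova_mean_squares(pairs)
    if msr == 0 and mse == 0 and msc == 0:
        raise ValueError("ICC undefined: zero total variance")

    if model == "icc3":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise ValueError("ICC undefined: zero variance")
        value = (msr - mse) / denom
        if mse == 0:
            return 1.0, (1.0, 1.0)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / sps.f.ppf(1 - ci_alpha / 2, df1, df2)
        f_u = f_obs * sps.f.ppf(1 - ci_alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
        return float(value), (float(lo), float(hi))

    if model != "icc2":
        raise ValueError(f"unknown ICC model {model!r}")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero variance")
    value = (msr - mse) / denom
    if mse == 0 and msc == mse:
        return 1.0, (1.0, 1.0)

    # McGraw & Wong CI for ICC(A,1) via Satterthwaite degrees of freedom
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_star1 = sps.f.ppf(1 - ci_alpha / 2, n - 1, v)
        f_star2 = sps.f.ppf(1 - ci_alpha / 2, v, n - 1)
        lo = n * (msr - f_star1 * mse) / (
            f_star1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_star2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star2 * msr
        )
    else:
        lo = hi = 1.0
    return float(value), (float(lo), float(hi))


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Bland-Altman agreement: mean difference and 1.96-sd limits of
    agreement, plus the (pair mean, pair difference) scatter for plotting."""
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.diffs
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return (
        mean_diff,
        mean_diff - 1.96 * sd,
        mean_diff + 1.96 * sd,
        pairs.means,
        d,
    )


def paired_ttest(pairs: PairedMeasurements) -> tuple[float, float, int]:
    """Two-tailed paired Student's t-test; returns (t, p, df)."""
    if pairs.n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = pairs.diffs
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired t-test undefined: zero-variance differences")
    res = sps.ttest_rel(pairs.x1, pairs.x2)
    return float(res.statistic), float(res.pvalue), pairs.n - 1


def classify_agreement(icc_value: float) -> str:
    """Agreement category: excellent above 0.75, good in [0.40, 0.75],
    poor below 0.40."""
    if not -1.0 <= icc_value <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if icc_value > 0.75:
        return "excellent"
    if icc_value >= 0.40:
        return "good"
    return "poor"


def repeatability_summary(pairs: PairedMeasurements, icc_model: str = "icc2") -> RepeatabilityResult:
    """All repeatability statistics for one paired measurement set.

    Degenerate perfect agreement (identical vectors) is reported as the
    perfect-agreement sentinel: ICC 1, CoV 0, zero-width limits, no t-test.
    """
    d = pairs.diffs
    if np.allclose(d, 0) and np.std(pairs.x1) > 0:
        return RepeatabilityResult(
            icc=1.0,
            icc_ci=(1.0, 1.0),
            cov_percent=0.0,
            bland_altman=(0.0, 0.0, 0.0),
            ttest=(0.0, 1.0, pairs.n - 1),
            category="excellent",
            n=pairs.n,
            icc_model=icc_model,
        )
    value, ci = icc(pairs, model=icc_model)
    mean_diff, lo, hi, _, _ = bland_altman(pairs)
    try:
        t = paired_ttest(pairs)
    except ValueError:
        t = (np.nan, np.nan, pairs.n - 1)
    return RepeatabilityResult(
        icc=value,
        icc_ci=ci,
        cov_percent=cov(pairs),
        bland_altman=(mean_diff, lo, hi),
        ttest=t,
        category=classify_agreement(np.clip(value, -1, 1)),
        n=pairs.n,
        icc_model=icc_model,
    )
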