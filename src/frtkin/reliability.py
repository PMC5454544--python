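"""Normality testing, paired comparisons and intraclass correlation.

The reliability questions are the classic repeated-measures ones: do
three repetitions of the reach, read by one observer, give the same
numbers (intraobserver), and do two observers reading the same trials
agree (interobserver)?  Both are answered with the intraclass
correlation coefficient from the two-way random-effects ANOVA,
absolute-agreement, single-measures form — ICC(2,1) in the
Shrout–Fleiss taxonomy — with 95% confidence bounds from the
F distribution.  The consistency form ICC(3,1), which forgives a
constant rater offset, is available by flag; the model label always
travels with the estimate.

Placement comparisons use a Kolmogorov–Smirnov (Lilliefors) normality
gate: paired Student t when the paired differences look normal, the
Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import (
    DegenerateMatrix,
    InsufficientData,
    LengthMismatch,
    MissingVariable,
)

#: Qualitative correlation bands, closed on both ends as printed:
#: very low 0-.29, low .30-.49, moderate .50-.69, high .70-.89,
#: very high >= .90.  Negative estimates fall in very_low.
BANDS = (
    (0.30, "very_low"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (np.inf, "very_high"),
)

ICC_FORMS = ("ICC(2,1)", "ICC(3,1)")
_FORM_ALIASES = {
    "ICC(2,1)": "ICC(2,1)", "icc2": "ICC(2,1)", "agreement": "ICC(2,1)",
    "ICC(3,1)": "ICC(3,1)", "icc3": "ICC(3,1)", "consistency": "ICC(3,1)",
}
_FORM_LABELS = {
    "ICC(2,1)": "ICC(2,1) two-way random effects, absolute agreement, single measures",
    "ICC(3,1)": "ICC(3,1) two-way mixed effects, consistency, single measures",
}


def classify_icc(value: float) -> str:
    """Qualitative band of an ICC estimate."""
    if value > 1.0 + 1e-12:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    for upper, band in BANDS:
        if value < upper:
            return band
    return "very_high"


def ks_normality(sample: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean and SD.

    The p-value carries the Lilliefors correction (the naive KS p-value
    is anti-conservative when the parameters are estimated from the
    sample).  Needs n >= 4.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise InsufficientData(f"normality test needs n >= 4, got {x.size}")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


@dataclass(frozen=True)
class ComparisonResult:
    """A paired trunk-vs-lumbar (or any paired) comparison of one variable."""

    variable: str
    normality_p: float
    method: str                # 'student_t' or 'wilcoxon'
    mean_difference: float
    statistic: float
    p_value: float
    significant: bool
    n: int


def paired_compare(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
) -> ComparisonResult:
    """Compare paired measurements, choosing the test from the data.

    The paired differences are gated through :func:`ks_normality`:
    Student's paired t when normality is not rejected at ``alpha``,
    Wilcoxon's signed-rank otherwise (zeros dropped; exact null
    distribution up to n = 25, normal approximation with continuity
    correction above).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatch(f"paired samples of lengths {x.size} and {y.size}")
    if x.size < 4:
        raise InsufficientData(f"paired comparison needs n >= 4, got {x.size}")
    d = x - y
    mean_diff = float(d.mean())

    if np.ptp(d) == 0.0:
        # identical differences carry no sampling variability to test
        p = 1.0 if d[0] == 0.0 else 0.0
        return ComparisonResult(variable, np.nan, "student_t", mean_diff,
                                np.nan, p, p <= alpha, int(d.size))

    _, p_norm = ks_normality(d)
    if p_norm > alpha:
        res = stats.ttest_rel(x, y)
        method, statistic, p = "student_t", float(res.statistic), float(res.pvalue)
    else:
        dz = d[d != 0.0]
        exact_ok = dz.size <= 25 and np.unique(np.abs(dz)).size == dz.size
        res = stats.wilcoxon(
            d,
            zero_method="wilcox",
            correction=True,
            method="exact" if exact_ok else "approx",
        )
        method, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return ComparisonResult(variable, float(p_norm), method, mean_diff,
                            statistic, p, p <= alpha, int(d.size))


@dataclass
class RatingsMatrix:
    """Subjects x columns grid of one variable's measurements.

    Columns are repetitions (mode 'intraobserver') or raters (mode
    'interobserver'); the grid must be complete.
    """

    values: np.ndarray
    mode: str = "interobserver"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x columns grid")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 columns, got {n} x {k}")
        if not np.isfinite(self.values).all():
            raise ValueError("ratings grid must be listwise-complete and finite")

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class ReliabilityResult:
    """An ICC point estimate with its 95% CI and qualitative band."""

    icc: float
    ci_low: float
    ci_high: float
    band: str
    model_label: str
    n_subjects: int
    n_columns: int


def _anova_mean_squares(Y: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x columns) ANOVA mean squares: MSR, MSC, MSE."""
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((Y - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc(
    matrix: RatingsMatrix,
    form: str = "ICC(2,1)",
    alpha: float = 0.05,
) -> ReliabilityResult:
    """Single-measures intraclass correlation with F-based CI.

    Default is the two-way random-effects absolute-agreement form
    ICC(2,1); ``form='ICC(3,1)'`` gives the consistency form.  Raises
    :class:`DegenerateMatrix` when the grid has zero total variance.
    """
    try:
        form = _FORM_ALIASES[form]
    except KeyError:
        raise ValueError(f"unknown ICC form {form!r}; use one of {ICC_FORMS}") from None
    Y = matrix.values
    n, k = Y.shape
    if np.ptp(Y) == 0.0:
        raise DegenerateMatrix("all ratings identical: ICC undefined")
    msr, msc, mse = _anova_mean_squares(Y)

    if form == "ICC(3,1)":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0.0:
            lo, hi = est, est
        else:
            fobs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0.0 and msc == 0.0:
            lo, hi = 1.0, 1.0
        else:
            # Satterthwaite df for the rater+error composite (McGraw & Wong)
            if est >= 1.0:
                lo, hi = 1.0, 1.0
            else:
                a = k * est / (n * (1.0 - est))
                b = 1.0 + k * est * (n - 1) / (n * (1.0 - est))
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else k - 1
                f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )

    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(min(lo, est), -1.0, 1.0))
    hi = float(np.clip(max(hi, est), -1.0, 1.0))
    return ReliabilityResult(
        icc=est,
        ci_low=lo,
        ci_high=hi,
        band=classify_icc(est),
        model_label=_FORM_LABELS[form],
        n_subjects=n,
        n_columns=k,
    )


def reliability_table(
    dataset: Mapping[str, Mapping[str, RatingsMatrix]],
    form: str = "ICC(2,1)",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per variable: intra- and inter-observer ICC with 95% CI.

    ``dataset`` maps variable name -> {'intraobserver': RatingsMatrix,
    'interobserver': RatingsMatrix}; a missing matrix raises
    :class:`MissingVariable` naming it.
    """
    rows = []
    for variable, matrices in dataset.items():
        row: dict = {"variable": variable}
        for mode in ("intraobserver", "interobserver"):
            if mode not in matrices:
                raise MissingVariable(f"{variable!r} lacks its {mode} ratings matrix")
            res = icc(matrices[mode], form=form, alpha=alpha)
            row[f"{mode}_icc"] = res.icc
            row[f"{mode}_ci_low"] = res.ci_low
            row[f"{mode}_ci_high"] = res.ci_high
            row[f"{mode}_band"] = res.band
        row["model_label"] = _FORM_LABELS[_FORM_ALIASES[form]]
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt3(x: float) -> str:
    """3-decimal, leading zero stripped: 0.872 -> '.872'."""
    s = f"{x:.3f}"
    return s.replace("0.", ".", 1) if abs(x) < 1 else s


def format_reliability_table(df: pd.DataFrame) -> pd.DataFrame:
    """Human-facing copy with '.872' style ICCs and '.857-.886' CIs."""
    out = pd.DataFrame({"variable": df["variable"]})
    for mode in ("intraobserver", "interobserver"):
        out[f"{mode}_icc"] = df[f"{mode}_icc"].map(_fmt3)
        out[f"{mode}_ci"] = [
            f"{_fmt3(lo)}-{_fmt3(hi)}"
            for lo, hi in zip(df[f"{mode}_ci_low"], df[f"{mode}_ci_high"])
        ]
    return out


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Per-variable comparison summary with the method flag and 'P=.02'
    style p-values."""
    rows = []
    for r in results:
        p = round(r.p_value, 2)
        rows.append({
            "variable": r.variable,
            "method": r.method,
            "mean_difference": r.mean_difference,
            "p_value": r.p_value,
            "p_label": ("P<.01" if p < 0.01 else f"P={p:.2f}".replace("0.", ".", 1)),
            "significant": r.significant,
            "n": r.n,
        })
    return pd.DataFrame(rows)
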