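"""Method-agreement and outcome statistics for CER measurement series.

Covers the evaluation toolkit used to validate an automated CER
measurement against a manual reference: paired t-test of pre/post
change, one-way ANOVA across measurement methods, intraclass
correlation (two-way single-measure, absolute-agreement or consistency
form) with F-based 95% confidence bounds and the conventional
interpretation bands, Bland–Altman bias with 95% limits of agreement,
ptosis severity classification, pre/post improvement rate, and a
cohort-level report assembling all of the above.

Two eyes per patient are treated as independent observations (matching
common practice in bilateral-ptosis cohorts); clustering by patient is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateVarianceError, ValidationError

LOA_MULTIPLIER = 1.96  # 95% limits of agreement; no small-sample t-correction

#: ICC interpretation cut-points: moderate 0.41–0.6, substantial
#: 0.6–0.8, excellent 0.8–1.0.
ICC_BANDS = ((0.41, "moderate"), (0.6, "substantial"), (0.8, "excellent"))

SEVERITY_THRESHOLD_MM = 2.0


@dataclass(frozen=True)
class MeasurementSeries:
    """One method's CER values over a cohort of eyes, in percent."""

    values: np.ndarray
    eye_ids: tuple[str, ...] | None = None
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValidationError("series values must be one-dimensional")
        if np.isnan(self.values).any():
            raise ValidationError("series contains missing values")
        if ((self.values < 0) | (self.values > 100)).any():
            raise ValidationError("CER values must lie in [0, 100]")
        if self.eye_ids is not None and len(self.eye_ids) != len(self.values):
            raise ValidationError("eye_ids length does not match values")

    def __len__(self) -> int:
        return len(self.values)


def _as_values(series) -> np.ndarray:
    if isinstance(series, MeasurementSeries):
        return series.values
    return np.asarray(series, dtype=float)


def _check_paired(a: np.ndarray, b: np.ndarray, min_n: int) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"paired series must have equal length, got {a.shape} vs {b.shape}")
    if len(a) < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {len(a)}")


def paired_t(pre, post) -> tuple[float, float]:
    """Two-sided paired t-test on matched series.

    Identical series return (0, 1) by convention; constant non-zero
    differences have zero variance and raise
    :class:`DegenerateVarianceError` rather than returning an infinite
    statistic.
    """
    a, b = _as_values(pre), _as_values(post)
    _check_paired(a, b, 2)
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "paired differences are constant and non-zero; t statistic is undefined"
        )
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float | None
    ci_high: float | None
    band: str
    degenerate: bool = False

    def __iter__(self):  # (icc, (lo, hi)) unpacking
        yield self.icc
        yield (self.ci_low, self.ci_high)


def icc_band(icc: float) -> str:
    label = "poor"
    for cut, name in ICC_BANDS:
        if icc >= cut:
            label = name
    return label


def _mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares of an
    n×k two-way crossed layout, by explicit sums of squares."""
    n, k = data.shape
    gm = data.mean()
    ssr = k * np.sum((data.mean(axis=1) - gm) ** 2)
    ssc = n * np.sum((data.mean(axis=0) - gm) ** 2)
    sst = np.sum((data - gm) ** 2)
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_agreement(a, b, form: str = "absolute_agreement", alpha: float = 0.05) -> ICCResult:
    """Two-way single-measure intraclass correlation between two series.

    ``form`` selects absolute agreement (sensitive to systematic offsets;
    the appropriate form for method comparison) or consistency.  The 95%
    confidence interval uses the standard F-distribution bounds.  Exactly
    identical series return ICC 1.0 by convention with a degenerate
    (point) interval, since the variance components collapse.
    """
    x, y = _as_values(a), _as_values(b)
    _check_paired(x, y, 3)
    if form not in ("absolute_agreement", "consistency"):
        raise ValidationError(f"unknown ICC form {form!r}")
    if np.array_equal(x, y):
        return ICCResult(1.0, 1.0, 1.0, icc_band(1.0), degenerate=True)
    data = np.column_stack([x, y])
    if np.ptp(data) == 0:
        raise DegenerateVarianceError("ICC undefined: zero total variance")
    n, k = data.shape
    msr, msc, mse = _mean_squares(data)

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # perfect consistency (e.g. constant offset): point interval
            return ICCResult(float(icc), 1.0, 1.0, icc_band(float(icc)), degenerate=True)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        a_ = (k * icc) / (n * (1 - icc))
        b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(float(icc), float(lo), float(hi), icc_band(float(icc)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between two paired series."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)

    def __iter__(self):
        yield self.bias
        yield self.loa_low
        yield self.loa_high


def bland_altman(a, b) -> BlandAltmanResult:
    """Differences d = a − b; bias = mean(d); LoA = bias ± 1.96·SD(d)."""
    x, y = _as_values(a), _as_values(b)
    _check_paired(x, y, 2)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        means=(x + y) / 2.0,
        differences=d,
    )


def one_way_anova(series: list) -> tuple[float, float]:
    """Between/within mean-square F ratio across measurement methods."""
    groups = [_as_values(s) for s in series]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValidationError("each group needs at least two observations")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        raise DegenerateVarianceError("one-way ANOVA undefined: zero variance everywhere")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def improvement_rate(pre_mean: float, post_mean: float) -> float:
    """Relative pre→post change, 100 × (post − pre) / pre, to 2 decimals."""
    if pre_mean <= 0:
        raise ValidationError("pre_mean must be positive")
    return round(100.0 * (post_mean - pre_mean) / pre_mean, 2)


@dataclass(frozen=True)
class SeverityClass:
    label: str
    droop_mm: float


def classify_severity(droop_mm: float, threshold_mm: float = SEVERITY_THRESHOLD_MM) -> SeverityClass:
    """Mild iff droop ≤ threshold (default 2 mm); else moderate-to-severe."""
    if droop_mm < 0:
        raise ValidationError("droop_mm must be non-negative")
    label = "mild" if droop_mm <= threshold_mm else "moderate_to_severe"
    return SeverityClass(label=label, droop_mm=float(droop_mm))


def two_way_anova(df: pd.DataFrame, value: str = "cer", factor_a: str = "severity", factor_b: str = "timepoint") -> pd.DataFrame:
    """Two-way ANOVA (factor_a × factor_b) via an OLS fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


# ---------------------------------------------------------------------------
# Cohort report

LONG_COLUMNS = ("eye_id", "timepoint", "method", "cer", "droop_mm")

SUMMARY_COLUMNS = ("method", "pre_mean", "pre_sd", "post_mean", "post_sd", "t", "p", "n")
AGREEMENT_COLUMNS = (
    "timepoint", "method_a", "method_b", "icc", "icc_ci_low", "icc_ci_high",
    "icc_band", "bias", "loa_low", "loa_high", "n",
)
SEVERITY_COLUMNS = (
    "severity", "n_eyes", "pre_mean", "pre_sd", "post_mean", "post_sd", "improvement_rate",
)


@dataclass(frozen=True)
class CohortReport:
    """Assembled pre/post, agreement and severity tables for one cohort."""

    summary: pd.DataFrame
    agreement: pd.DataFrame
    severity: pd.DataFrame
    anova_two_way: pd.DataFrame | None
    exclusions: pd.DataFrame


def _validate_long(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LONG_COLUMNS if c not in df.columns and c != "droop_mm"]
    if missing:
        raise ValidationError(f"long-format table missing column(s): {missing}")
    bad = df[~df["timepoint"].isin(["pre", "post"])]
    if len(bad):
        raise ValidationError(
            f"timepoint must be 'pre' or 'post'; offending rows: {list(bad.index[:10])}"
        )
    dup = df.duplicated(subset=["eye_id", "timepoint", "method"])
    if dup.any():
        raise ValidationError(
            f"duplicate (eye_id, timepoint, method) rows: {list(df.index[dup][:10])}"
        )
    return df


def cohort_report(long_df: pd.DataFrame, severity_method: str | None = None) -> CohortReport:
    """Full agreement/outcome report from a long-format measurement table.

    Expects columns ``eye_id, timepoint, method, cer`` and optionally
    ``droop_mm``; ``timepoint`` is 'pre' or 'post'.  Eyes missing either
    timepoint for a method are excluded from that method's paired
    statistics and listed in the exclusions table.  Cross-method ICC and
    Bland–Altman are computed per timepoint over eyes shared by both
    methods.  With droop present, severity-stratified means, improvement
    rates and a severity × timepoint two-way ANOVA are included (using
    ``severity_method``, default the first method).
    """
    df = _validate_long(long_df.copy())
    methods = sorted(df["method"].unique())
    wide = df.pivot_table(index="eye_id", columns=["method", "timepoint"], values="cer")

    summary_rows, exclusion_rows = [], []
    for m in methods:
        sub = wide[m] if m in wide.columns.get_level_values(0) else pd.DataFrame()
        for tp in ("pre", "post"):
            if tp not in sub.columns:
                sub[tp] = np.nan
        complete = sub.dropna(subset=["pre", "post"])
        for eye_id in sub.index[sub[["pre", "post"]].isna().any(axis=1)]:
            missing_tp = [tp for tp in ("pre", "post") if pd.isna(sub.loc[eye_id, tp])]
            exclusion_rows.append(
                {"eye_id": eye_id, "method": m, "reason": f"missing timepoint(s): {missing_tp}"}
            )
        if len(complete) >= 2:
            try:
                t, p = paired_t(complete["pre"].to_numpy(), complete["post"].to_numpy())
            except DegenerateVarianceError:
                t, p = np.nan, np.nan
        else:
            t, p = np.nan, np.nan
        summary_rows.append({
            "method": m,
            "pre_mean": complete["pre"].mean(), "pre_sd": complete["pre"].std(ddof=1),
            "post_mean": complete["post"].mean(), "post_sd": complete["post"].std(ddof=1),
            "t": t, "p": p, "n": len(complete),
        })

    agreement_rows = []
    for tp in ("pre", "post"):
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                pair = pd.DataFrame({
                    "a": wide.get((ma, tp), pd.Series(dtype=float)),
                    "b": wide.get((mb, tp), pd.Series(dtype=float)),
                }).dropna()
                if len(pair) < 3:
                    continue
                icc = icc_agreement(pair["a"].to_numpy(), pair["b"].to_numpy())
                ba = bland_altman(pair["a"].to_numpy(), pair["b"].to_numpy())
                agreement_rows.append({
                    "timepoint": tp, "method_a": ma, "method_b": mb,
                    "icc": icc.icc, "icc_ci_low": icc.ci_low, "icc_ci_high": icc.ci_high,
                    "icc_band": icc.band, "bias": ba.bias,
                    "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": len(pair),
                })

    severity_rows: list[dict] = []
    anova_tbl = None
    if "droop_mm" in df.columns and df["droop_mm"].notna().any():
        sm_method = severity_method or methods[0]
        sev_df = df[df["method"] == sm_method].copy()
        sev_df["severity"] = [
            classify_severity(d).label for d in sev_df["droop_mm"].astype(float)
        ]
        for sev, grp in sev_df.groupby("severity"):
            piv = grp.pivot_table(index="eye_id", columns="timepoint", values="cer").dropna()
            if piv.empty or "pre" not in piv.columns or "post" not in piv.columns:
                continue
            pre_m, post_m = piv["pre"].mean(), piv["post"].mean()
            severity_rows.append({
                "severity": sev, "n_eyes": len(piv),
                "pre_mean": pre_m, "pre_sd": piv["pre"].std(ddof=1),
                "post_mean": post_m, "post_sd": piv["post"].std(ddof=1),
                "improvement_rate": improvement_rate(pre_m, post_m),
            })
        if sev_df["severity"].nunique() >= 2:
            anova_tbl = two_way_anova(sev_df.rename(columns={"cer": "cer"}))

    return CohortReport(
        summary=pd.DataFrame(summary_rows, columns=list(SUMMARY_COLUMNS)),
        agreement=pd.DataFrame(agreement_rows, columns=list(AGREEMENT_COLUMNS)),
        severity=pd.DataFrame(severity_rows, columns=list(SEVERITY_COLUMNS)),
        anova_two_way=anova_tbl,
        exclusions=pd.DataFrame(exclusion_rows, columns=["eye_id", "method", "reason"]),
    )
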