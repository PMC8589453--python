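"""Derived aging quantities and group-level statistics.

dAge = BA - CA (years of age acceleration); age ratio = BA / CA (a
point-in-time rate-of-aging surrogate: 1 means biological and calendar age
agree, > 1 means faster-than-calendar aging).  Groups are compared by mean
dAge difference with a two-sided Wilcoxon rank-sum (Mann-Whitney) test, and
each biomarker's association with the age ratio is summarised by a
univariate OLS fit on the raw (untransformed) marker values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError, StatisticsError

__all__ = [
    "GroupComparison",
    "RatioCorrelation",
    "compute_metrics",
    "compare_groups",
    "correlate_with_ratio",
]


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_diff_dage: float
    rank_test_p: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RatioCorrelation:
    biomarker: str
    slope: float
    r_squared: float
    p_value: float


def compute_metrics(results: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Join BA estimates to the cohort and derive dAge and age ratio.

    ``results`` must carry ``subject_id, ba, estimator``; ``cohort`` must
    carry ``subject_id, ca`` with strictly positive CA (the age ratio is a
    ratio of ages).  Output is one row per result row, in input order.
    """
    for col in ("subject_id", "ba", "estimator"):
        if col not in results.columns:
            raise SchemaError(f"results lack required column {col!r}")
    if "subject_id" not in cohort.columns or "ca" not in cohort.columns:
        raise SchemaError("cohort lacks 'subject_id'/'ca'")
    extra = [c for c in ("group", "gender") if c in cohort.columns]
    joined = results.merge(
        cohort[["subject_id", "ca", *extra]], on="subject_id", how="left",
        suffixes=("", "_cohort"),
    )
    if joined["ca"].isna().any():
        missing = joined.loc[joined["ca"].isna(), "subject_id"].tolist()
        raise SchemaError(f"no cohort row for subject(s) {missing[:5]}")
    if (joined["ca"] <= 0).any():
        raise DomainError("age ratio undefined: chronological age must be > 0")
    joined["dage"] = joined["ba"] - joined["ca"]
    joined["age_ratio"] = joined["ba"] / joined["ca"]
    return joined


def compare_groups(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    value_column: str = "dage",
    label_a: str | None = None,
    label_b: str | None = None,
) -> GroupComparison:
    """Mean dAge difference (a - b) with a two-sided rank-sum p-value.

    Works for any stratification: disease group vs matched controls, BMI
    bins, smoker vs non-smoker, and so on.
    """
    a = metrics_a[value_column].to_numpy(dtype=float)
    b = metrics_b[value_column].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each group needs at least 2 observations")

    def _label(df, given, default):
        if given:
            return given
        if "group" in df.columns and df["group"].nunique() == 1:
            return str(df["group"].iloc[0])
        return default

    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        group_a=_label(metrics_a, label_a, "a"),
        group_b=_label(metrics_b, label_b, "b"),
        mean_diff_dage=float(np.mean(a) - np.mean(b)),
        rank_test_p=float(stat.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def correlate_with_ratio(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: list[str] | tuple[str, ...],
) -> list[RatioCorrelation]:
    """Univariate OLS of age ratio on each raw biomarker, ranked by R^2.

    Raw (native-unit) marker values are used, so slopes are per clinical
    unit.  A constant biomarker yields an R^2 = 0 record with a warning.
    """
    joined = metrics[["subject_id", "age_ratio"]].merge(
        cohort[["subject_id", *panel]], on="subject_id", how="inner"
    )
    records = []
    ratio = joined["age_ratio"].to_numpy(dtype=float)
    for name in panel:
        x = joined[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(ratio))
        if np.std(x[ok]) == 0.0:
            warnings.warn(f"biomarker {name!r} is constant; correlation undefined")
            records.append(RatioCorrelation(name, 0.0, 0.0, float("nan")))
            continue
        fit = stats.linregress(x[ok], ratio[ok])
        records.append(
            RatioCorrelation(
                name, float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)
            )
        )
    records.sort(key=lambda r: r.r_squared, reverse=True)
    return records
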