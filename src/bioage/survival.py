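"""Survival validation of age acceleration.

Cox proportional-hazards models relate dAge (continuous, or dichotomised
at the in-sample median with the high arm defined as dAge >= median) to
time-to-event outcomes, optionally adjusted for covariates such as trial
arms and with an optional dAge x covariate interaction.  Kaplan-Meier
product-limit curves summarise group survival.  Fitting is delegated to
lifelines (Efron handling of tied event times; Wald intervals on the
log-hazard scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from .errors import ConvergenceError, FitError, SchemaError

__all__ = ["CoxResult", "fit_cox", "km_curve"]


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio for dAge (continuous or dichotomised), with Wald CI."""

    predictor: str  # "continuous" | "dichotomized-at-median"
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    events: int
    covariates: tuple[str, ...] = ()
    cut: float | None = None  # median used for dichotomisation
    interaction_with: str | None = None
    interaction_hr: float | None = None
    interaction_p: float | None = None


def fit_cox(
    records: pd.DataFrame,
    predictor: str = "continuous",
    covariates: list[str] | tuple[str, ...] = (),
    interaction_with: str | None = None,
    dage_column: str = "dage",
    time_column: str = "time",
    event_column: str = "event",
) -> CoxResult:
    """Cox PH fit of mortality on dAge.

    ``predictor="continuous"`` reports the hazard ratio per year of dAge;
    ``"dichotomized-at-median"`` splits at the in-sample median (high arm:
    dAge >= median) and reports the high-vs-low hazard ratio.  An optional
    interaction term (dAge term x ``interaction_with``) is reported with
    its own HR and p-value.
    """
    for col in (dage_column, time_column, event_column, *covariates):
        if col not in records.columns:
            raise SchemaError(f"records lack required column {col!r}")
    if interaction_with is not None and interaction_with not in records.columns:
        raise SchemaError(f"records lack interaction column {interaction_with!r}")

    events = int(records[event_column].sum())
    if events < 2:
        raise FitError(f"need at least 2 events to fit, have {events}")
    if covariates and records[list(covariates)].isna().any().any():
        raise FitError("missing covariate values")

    cut: float | None = None
    df = records[[time_column, event_column, *covariates]].copy()
    if predictor == "continuous":
        term = dage_column
        df[term] = records[dage_column].astype(float)
    elif predictor == "dichotomized-at-median":
        cut = float(records[dage_column].median())
        term = f"{dage_column}_high"
        df[term] = (records[dage_column] >= cut).astype(float)
    else:
        raise FitError(
            f"unknown predictor {predictor!r}; use 'continuous' or "
            "'dichotomized-at-median'"
        )

    inter_term = None
    if interaction_with is not None:
        if interaction_with not in df.columns:
            df[interaction_with] = records[interaction_with].astype(float)
        inter_term = f"{term}_x_{interaction_with}"
        df[inter_term] = df[term] * df[interaction_with]

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_column, event_col=event_column)
    except _LLConvergenceError as exc:  # pragma: no cover - pathological data
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc

    summary = cph.summary
    row = summary.loc[term]
    result = CoxResult(
        predictor=predictor,
        hazard_ratio=float(np.exp(row["coef"])),
        ci95=(
            float(np.exp(row["coef lower 95%"])),
            float(np.exp(row["coef upper 95%"])),
        ),
        p_value=float(row["p"]),
        n=len(records),
        events=events,
        covariates=tuple(covariates),
        cut=cut,
        interaction_with=interaction_with,
        interaction_hr=(
            float(np.exp(summary.loc[inter_term, "coef"])) if inter_term else None
        ),
        interaction_p=(
            float(summary.loc[inter_term, "p"]) if inter_term else None
        ),
    )
    return result


def km_curve(
    records: pd.DataFrame,
    groups: pd.Series | np.ndarray | list,
    time_column: str = "time",
    event_column: str = "event",
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per group.

    Returns ``{group: frame(time, survival)}``; every curve starts at
    (0, 1), is non-increasing and right-continuous, and censored subjects
    leave the risk set without a drop.
    """
    g = np.asarray(groups)
    if len(g) != len(records):
        raise SchemaError("groups vector length must match records")
    curves: dict[str, pd.DataFrame] = {}
    for level in pd.unique(g):
        mask = g == level
        kmf = KaplanMeierFitter()
        kmf.fit(
            records.loc[mask, time_column],
            records.loc[mask, event_column],
        )
        sf = kmf.survival_function_
        curves[str(level)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        ).reset_index(drop=True)
    return curves
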