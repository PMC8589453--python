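"""Cohort preparation: inclusion/exclusion rules, case-control matching and
the training split used to calibrate biological-age models.

Exclusion mirrors common survey practice for building a "metabolically
healthy" reference group: controls with HbA1c at or above the prediabetes
threshold (5.7%) are removed, as are rows with missing required values or
ages outside the study window.  Cases and controls are matched greedily by
nearest age within gender, without replacement, inside a caliper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, StratificationError

__all__ = [
    "ExclusionLog",
    "MatchResult",
    "apply_exclusions",
    "match_case_control",
    "train_test_split",
]


@dataclass
class ExclusionLog:
    """Per-rule removal counts, in the order the rules were applied."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, rule: str, removed: int) -> None:
        self.steps.append((rule, int(removed)))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)


@dataclass(frozen=True)
class MatchResult:
    """Age/gender matched pairs; unmatchable cases are reported, not fatal."""

    pairs: tuple[tuple[str, str], ...]
    unmatched_cases: tuple[str, ...]
    match_caliper: float


def apply_exclusions(
    table: pd.DataFrame,
    a1c_cutoff: float | None = 5.7,
    age_bounds: tuple[float, float] = (20.0, 80.0),
    required_columns: tuple[str, ...] | list[str] | None = None,
    a1c_column: str = "a1c",
    control_label: str = "control",
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study's inclusion rules and log removals per rule.

    Rules, in order: (1) control rows with A1c >= ``a1c_cutoff`` (strict
    "lower than" inclusion, so a control at exactly the cutoff is excluded);
    (2) rows missing any of ``required_columns``; (3) rows with CA outside
    ``age_bounds`` (inclusive).  Pass ``a1c_cutoff=None`` to skip rule 1.
    """
    required = list(required_columns or [])
    for col in required + ["ca"]:
        if col not in table.columns:
            raise SchemaError(f"required column {col!r} absent from table schema")

    log = ExclusionLog()
    df = table

    if a1c_cutoff is not None:
        if a1c_column not in df.columns:
            raise SchemaError(
                f"A1c column {a1c_column!r} absent but an A1c cutoff was requested"
            )
        is_control = df["group"].eq(control_label) if "group" in df.columns else True
        bad = is_control & (df[a1c_column] >= a1c_cutoff)
        log.add(f"control {a1c_column} >= {a1c_cutoff}", bad.sum())
        df = df.loc[~bad]

    if required:
        missing = df[required].isna().any(axis=1)
        log.add("missing required values", missing.sum())
        df = df.loc[~missing]

    lo, hi = age_bounds
    out_of_range = (df["ca"] < lo) | (df["ca"] > hi)
    log.add(f"age outside [{lo}, {hi}]", out_of_range.sum())
    df = df.loc[~out_of_range]

    return df.reset_index(drop=True), log


def match_case_control(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    caliper: float = 2.0,
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-age matching within gender, without replacement.

    Cases are processed in input order; each takes the still-available
    same-gender control with the smallest absolute age difference, provided
    it is within ``caliper`` years.  Exact ties in age distance are broken
    by a seeded random draw.  Each control is used at most once.
    """
    if cases.empty or controls.empty:
        raise ConfigurationError("both 'cases' and 'controls' must be non-empty")
    for df, name in ((cases, "cases"), (controls, "controls")):
        for col in ("subject_id", "ca", "gender"):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} absent from {name}")

    rng = np.random.default_rng(seed)
    ctrl_age = controls["ca"].to_numpy(dtype=float)
    ctrl_gender = controls["gender"].to_numpy()
    ctrl_id = controls["subject_id"].to_numpy()
    available = np.ones(len(controls), dtype=bool)

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for _, case in cases.iterrows():
        eligible = available & (ctrl_gender == case["gender"])
        if not eligible.any():
            unmatched.append(case["subject_id"])
            continue
        dist = np.abs(ctrl_age - float(case["ca"]))
        dist = np.where(eligible, dist, np.inf)
        best = dist.min()
        if best > caliper:
            unmatched.append(case["subject_id"])
            continue
        candidates = np.flatnonzero(dist == best)
        pick = candidates[rng.integers(len(candidates))]
        available[pick] = False
        pairs.append((case["subject_id"], ctrl_id[pick]))

    return MatchResult(tuple(pairs), tuple(unmatched), caliper)


def train_test_split(
    controls: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    gender_column: str = "gender",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive split of controls, stratified by gender.

    Each gender stratum contributes ``round(train_fraction * n)`` rows to
    the training set, so both per-gender models remain trainable.
    Membership is reproducible from ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(
            f"field 'train_fraction' must lie strictly in (0, 1), got {train_fraction}"
        )
    if gender_column not in controls.columns:
        raise SchemaError(f"required column {gender_column!r} absent from table schema")

    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for gender, stratum in controls.groupby(gender_column, sort=True):
        n = len(stratum)
        if n < 2:
            raise StratificationError(
                f"gender stratum {gender!r} has {n} row(s); need at least 2 to split"
            )
        order = rng.permutation(n)
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
        pos = stratum.index.to_numpy()
        train_idx.append(pos[order[:n_train]])
        test_idx.append(pos[order[n_train:]])

    train = controls.loc[np.concatenate(train_idx)].reset_index(drop=True)
    test = controls.loc[np.concatenate(test_idx)].reset_index(drop=True)
    return train, test
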