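"""Biomarker preprocessing: Box-Cox normalisation, standardisation,
winsorisation and gender adjustment.

The canonical order, recorded in :class:`TransformSpec`, is

    Box-Cox -> standardise -> winsorise -> gender-adjust

with every parameter (lambda, mean/sd, winsor clip values, per-gender
offsets) fitted on training controls and frozen before being applied to
held-out or disease-group data, so no information leaks from the groups
being compared into the reference transforms.

Markers containing non-positive values are left untransformed by default
(the ``skip`` policy), matching how an approximately normal marker with a
stray zero is handled in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import AdjustmentError, ConfigurationError, DomainError

__all__ = [
    "box_cox_fit_transform",
    "skip_transform_if_nonpositive",
    "winsorize",
    "gender_adjust",
    "TransformSpec",
    "Preprocessor",
]

_LAMBDA_BOUNDS = (-5.0, 5.0)


def box_cox_fit_transform(
    values: np.ndarray | pd.Series,
    lmbda: float | None = None,
    name: str = "biomarker",
) -> tuple[np.ndarray, float]:
    """Box-Cox transform with maximum-likelihood lambda.

    The transform is ``(x**lam - 1) / lam`` for ``lam != 0`` and ``ln(x)``
    at ``lam == 0``.  When ``lmbda`` is None, lambda maximises the profile
    log-likelihood over [-5, 5] (bounded scalar minimisation, absolute
    tolerance 1e-6).  Returns ``(transformed, lambda)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigurationError(f"{name}: need at least 2 values to transform")
    if np.any(x <= 0):
        raise DomainError(
            f"{name}: Box-Cox requires strictly positive values "
            "(shift the data or use the skip policy)"
        )
    if lmbda is None:
        res = optimize.minimize_scalar(
            lambda lam: -stats.boxcox_llf(lam, x),
            bounds=_LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-6},
        )
        lmbda = float(res.x)
    return special.boxcox(x, lmbda), float(lmbda)


def skip_transform_if_nonpositive(values: np.ndarray | pd.Series) -> str:
    """Return ``"skip"`` when any value is <= 0, else ``"transform"``.

    Box-Cox is undefined at zero or below; rather than shifting, a marker
    with non-positive observations is carried through untransformed.
    """
    x = np.asarray(values, dtype=float)
    return "skip" if np.any(x[~np.isnan(x)] <= 0) else "transform"


def winsorize(
    values: np.ndarray | pd.Series,
    limits: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Shrink values beyond the given percentiles to those percentiles.

    Percentile bounds are order statistics of the input (``method="lower"``),
    which makes the operation idempotent: re-winsorising an already
    winsorised vector changes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ConfigurationError("winsorize: need at least 3 values")
    lo_p, hi_p = limits
    if not (0.0 <= lo_p < hi_p <= 100.0):
        raise ConfigurationError(
            f"winsorize: limits must satisfy 0 <= lower < upper <= 100, got {limits}"
        )
    lo = np.nanpercentile(x, lo_p, method="lower")
    hi = np.nanpercentile(x, hi_p, method="lower")
    return np.clip(x, lo, hi)


def gender_adjust(
    values: np.ndarray | pd.Series,
    gender: np.ndarray | pd.Series,
) -> np.ndarray:
    """Remove the gender mean difference, preserving the grand mean.

    Equivalent to the residuals of an OLS regression of the values on a
    gender indicator, plus the grand mean; per-gender means are equalised.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(gender)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise AdjustmentError(
            "gender adjustment requires both genders in the data; "
            f"found only {list(levels)}"
        )
    grand = np.nanmean(x)
    out = x.copy()
    for level in levels:
        mask = g == level
        out[mask] = x[mask] - np.nanmean(x[mask]) + grand
    return out


@dataclass
class TransformSpec:
    """Frozen preprocessing parameters for one biomarker.

    ``box_cox_lambda`` is a float, or the string ``"skipped"`` when the
    marker contained non-positive values.  ``winsor_bounds`` are clip values
    on the standardised scale, computed from training data.
    ``gender_offsets`` map gender label -> (training mean of that gender
    minus the grand mean), subtracted at application time.
    """

    box_cox_lambda: float | str
    standardize_mean: float
    standardize_sd: float
    winsor_limits: tuple[float, float]
    winsor_bounds: tuple[float, float]
    gender_adjust: bool
    gender_offsets: dict[str, float] = field(default_factory=dict)

    def apply(self, values: np.ndarray, gender: np.ndarray | None = None) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.box_cox_lambda != "skipped":
            if np.any(x[~np.isnan(x)] <= 0):
                raise DomainError(
                    "non-positive value in a marker whose fitted transform is "
                    "Box-Cox; refit with the skip policy or clean the data"
                )
            x = special.boxcox(x, float(self.box_cox_lambda))
        x = (x - self.standardize_mean) / self.standardize_sd
        x = np.clip(x, *self.winsor_bounds)
        if self.gender_adjust:
            if gender is None:
                raise AdjustmentError("gender vector required to apply this spec")
            g = np.asarray(gender)
            offsets = np.zeros_like(x)
            for level, off in self.gender_offsets.items():
                offsets[g == level] = off
            x = x - offsets
        return x


class Preprocessor:
    """Fits and applies the full per-biomarker transform chain.

    Fit on training controls only; ``transform`` then applies the frozen
    parameters to any table (held-out controls, disease groups).
    """

    def __init__(
        self,
        biomarkers: list[str] | tuple[str, ...],
        winsor_limits: tuple[float, float] = (1.0, 99.0),
        use_box_cox: bool = True,
        adjust_gender: bool = True,
    ) -> None:
        self.biomarkers = tuple(biomarkers)
        self.winsor_limits = winsor_limits
        self.use_box_cox = use_box_cox
        self.adjust_gender = adjust_gender
        self.specs: dict[str, TransformSpec] = {}

    def fit(self, train: pd.DataFrame, gender_column: str = "gender") -> "Preprocessor":
        gender = train[gender_column].to_numpy() if self.adjust_gender else None
        for name in self.biomarkers:
            x = train[name].to_numpy(dtype=float)
            finite = x[~np.isnan(x)]
            if self.use_box_cox and skip_transform_if_nonpositive(finite) == "transform":
                xt, lam = box_cox_fit_transform(finite, name=name)
                lam_rec: float | str = lam
            else:
                xt, lam_rec = finite, "skipped"
            mean = float(np.mean(xt))
            sd = float(np.std(xt, ddof=1))
            if sd <= 0:
                raise ConfigurationError(f"{name}: zero variance; cannot standardise")
            z = (xt - mean) / sd
            lo = float(np.percentile(z, self.winsor_limits[0], method="lower"))
            hi = float(np.percentile(z, self.winsor_limits[1], method="lower"))
            offsets: dict[str, float] = {}
            if self.adjust_gender:
                zw = np.clip(z, lo, hi)
                g = gender[~np.isnan(x)]
                grand = float(np.mean(zw))
                for level in pd.unique(g):
                    offsets[str(level)] = float(np.mean(zw[g == level]) - grand)
            self.specs[name] = TransformSpec(
                box_cox_lambda=lam_rec,
                standardize_mean=mean,
                standardize_sd=sd,
                winsor_limits=self.winsor_limits,
                winsor_bounds=(lo, hi),
                gender_adjust=self.adjust_gender,
                gender_offsets=offsets,
            )
        return self

    def transform(self, table: pd.DataFrame, gender_column: str = "gender") -> pd.DataFrame:
        if not self.specs:
            raise ConfigurationError("Preprocessor.transform called before fit")
        out = table.copy()
        gender = table[gender_column].to_numpy() if self.adjust_gender else None
        for name in self.biomarkers:
            out[name] = self.specs[name].apply(
                table[name].to_numpy(dtype=float), gender
            )
        return out

    def fit_transform(self, train: pd.DataFrame, gender_column: str = "gender") -> pd.DataFrame:
        return self.fit(train, gender_column).transform(train, gender_column)
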