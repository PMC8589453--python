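"""Phenotypic Age: a fixed-coefficient biological-age formula built from
nine blood biomarkers plus chronological age.

The linear predictor is

    xb = intercept
         - 0.0336 * albumin[g/L]       + 0.0095 * creatinine[umol/L]
         + 0.0195 * glucose[mmol/L]    + 0.0954 * ln(CRP[mg/dL])
         - 0.0120 * lymphocyte%        + 0.0268 * MCV[fL]
         + 0.3356 * RDW[%]             + 0.00188 * ALP[U/L]
         + 0.0554 * WBC[1000/uL]       + 0.0804 * CA[years]

and the outer map is

    PhAge = 141.50 + ln(-0.0053 * ln(1 - xb)) / 0.09165.

Two coefficient variants are provided.  ``"levine-sign"`` (default) reads
-19.907 as a stand-alone intercept with the albumin coefficient -0.0336,
which is the only reading under which xb is a well-formed linear score.
``"paper-printed"`` follows the alternative literal reading in which the
leading term is the product -19.907 * 0.0336 * albumin (no separate
intercept); it is retained purely for fidelity audits.

Domain: the outer map needs 0 < xb < 1 (so that ln(1 - xb) < 0 and the
argument of the outer logarithm is positive).  Because this form feeds the
raw linear score into ln(1 - xb) — rather than a mortality probability, as
in Levine's original Gompertz-CDF construction — typical human marker
values put xb far below 0 and the formula is undefined there.  The
implementation is faithful to the stated form and raises a per-subject
domain error naming the offending term; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd

from .errors import DomainError, PanelError, PredictionError
from .simulate import PHAGE_MARKERS

__all__ = ["PhAgeSpec", "compute_phage"]

_XB_COEFFS = MappingProxyType(
    {
        "albumin": -0.0336,
        "creatinine": 0.0095,
        "glucose": 0.0195,
        "log_crp": 0.0954,
        "lymphocyte_pct": -0.0120,
        "mcv": 0.0268,
        "rdw": 0.3356,
        "alp": 0.00188,
        "wbc": 0.0554,
        "ca": 0.0804,
    }
)

_INTERCEPT = -19.907
_OUTER_OFFSET = 141.50
_OUTER_SCALE = 0.0053
_OUTER_DENOM = 0.09165

_VARIANTS = ("levine-sign", "paper-printed")


@dataclass(frozen=True)
class PhAgeSpec:
    """Immutable Phenotypic-Age coefficient set.

    ``variant`` selects the reading of the leading xb term (see module
    docstring).  Coefficients and outer constants are fixed per variant.
    """

    variant: str = "levine-sign"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise PanelError(
                f"unknown Phenotypic-Age variant {self.variant!r}; "
                f"choose from {_VARIANTS}"
            )

    @property
    def coefficients(self) -> dict[str, float]:
        """Linear-term coefficients, keyed by marker (``log_crp`` for the
        ln(CRP) term, ``ca`` for chronological age)."""
        coeffs = dict(_XB_COEFFS)
        if self.variant == "paper-printed":
            # literal reading: leading product replaces intercept + albumin term
            coeffs["albumin"] = _INTERCEPT * 0.0336
        return coeffs

    @property
    def intercept(self) -> float:
        return _INTERCEPT if self.variant == "levine-sign" else 0.0

    @property
    def outer_constants(self) -> tuple[float, float, float]:
        return (_OUTER_OFFSET, _OUTER_SCALE, _OUTER_DENOM)


def linear_predictor(subjects: pd.DataFrame, spec: PhAgeSpec) -> np.ndarray:
    """The xb score for each subject (markers in Levine units)."""
    for col in PHAGE_MARKERS + ("ca",):
        if col not in subjects.columns:
            raise PredictionError(f"column {col!r} absent; required for PhAge")
    crp = subjects["crp"].to_numpy(dtype=float)
    if np.any(crp <= 0):
        bad = subjects.loc[crp <= 0, "subject_id"].tolist()
        raise DomainError(
            f"ln(CRP) undefined: non-positive CRP for subject(s) {bad[:5]}"
        )
    coeffs = spec.coefficients
    xb = np.full(len(subjects), spec.intercept, dtype=float)
    for marker in PHAGE_MARKERS:
        if marker == "crp":
            xb += coeffs["log_crp"] * np.log(crp)
        else:
            xb += coeffs[marker] * subjects[marker].to_numpy(dtype=float)
    xb += coeffs["ca"] * subjects["ca"].to_numpy(dtype=float)
    return xb


def compute_phage(
    subjects: pd.DataFrame,
    spec: PhAgeSpec | None = None,
) -> pd.DataFrame:
    """Phenotypic Age per subject.

    Requires all nine markers plus CA in Levine units (use
    :func:`bioage.units.unit_convert` to convert survey units).  Raises
    :class:`~bioage.errors.DomainError` naming the subjects and the
    offending term when xb leaves the domain of the outer map.
    Returns a frame with ``subject_id, ba, estimator, panel_id, gender``
    plus the ``variant`` used.
    """
    spec = spec or PhAgeSpec()
    xb = linear_predictor(subjects, spec)

    bad_outer = 1.0 - xb <= 0.0
    if np.any(bad_outer):
        ids = subjects.loc[bad_outer, "subject_id"].tolist()
        raise DomainError(
            f"1 - xb <= 0 (xb >= 1) for subject(s) {ids[:5]}: "
            "ln(1 - xb) undefined"
        )
    inner = -_OUTER_SCALE * np.log(1.0 - xb)
    bad_inner = inner <= 0.0
    if np.any(bad_inner):
        ids = subjects.loc[bad_inner, "subject_id"].tolist()
        raise DomainError(
            f"-{_OUTER_SCALE} * ln(1 - xb) <= 0 for subject(s) {ids[:5]} "
            "(xb <= 0): argument of the outer logarithm is non-positive"
        )
    phage = _OUTER_OFFSET + np.log(inner) / _OUTER_DENOM

    gender = (
        subjects["gender"].astype(str).to_numpy()
        if "gender" in subjects.columns
        else np.full(len(subjects), "", dtype=object)
    )
    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "ba": phage,
            "estimator": "phage",
            "panel_id": "phage9",
            "gender": gender,
            "variant": spec.variant,
        }
    )
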