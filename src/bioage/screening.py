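"""Biomarker screening against chronological age.

A candidate biomarker is retained when its univariate OLS regression on CA
is significant; pairs of biomarkers that are nearly collinear are flagged
as redundant; and a biomarker whose univariate R-squared with CA is too
high is flagged for the "CA paradox" (it would dominate the biological-age
estimate and simply reproduce CA).  Both flags are advisory: flagged
markers are reported, not silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, PanelError

__all__ = [
    "ScreenReport",
    "univariate_screen",
    "redundancy_check",
    "ca_paradox_flag",
]

CA_PARADOX_THRESHOLD = 0.32


@dataclass
class ScreenReport:
    """Per-biomarker screening outcome plus redundancy flags."""

    table: pd.DataFrame
    p_threshold: float
    paradox_threshold: float
    redundancy_drops: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "biomarker"].tolist()


def ca_paradox_flag(r_squared: float, threshold: float = CA_PARADOX_THRESHOLD) -> bool:
    """True when a biomarker's CA R-squared strictly exceeds the threshold.

    Such markers are too collinear with CA to add independent information;
    they are flagged but conventionally retained.
    """
    if not 0.0 <= r_squared <= 1.0:
        raise DomainError(f"r_squared must lie in [0, 1], got {r_squared}")
    return r_squared > threshold


def univariate_screen(
    table: pd.DataFrame,
    biomarkers: list[str] | tuple[str, ...],
    ca_column: str = "ca",
    p_threshold: float = 0.05,
    paradox_threshold: float = CA_PARADOX_THRESHOLD,
) -> ScreenReport:
    """Screen each biomarker by an OLS slope test against CA.

    Expects preprocessed (transformed/standardised/winsorised/
    gender-adjusted) data.  A zero-variance biomarker is reported with
    ``selected=False`` and a warning rather than raising.
    """
    ca = table[ca_column].to_numpy(dtype=float)
    rows = []
    for name in biomarkers:
        x = table[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(ca))
        if np.std(x[ok]) == 0.0:
            warnings.warn(f"biomarker {name!r} has zero variance; not selected")
            rows.append((name, np.nan, 0.0, False, False))
            continue
        fit = stats.linregress(ca[ok], x[ok])
        r2 = float(fit.rvalue**2)
        rows.append(
            (name, float(fit.pvalue), r2, fit.pvalue < p_threshold,
             ca_paradox_flag(r2, paradox_threshold))
        )
    report = pd.DataFrame(
        rows, columns=["biomarker", "p_value", "r_squared", "selected", "ca_paradox_flag"]
    )
    return ScreenReport(report, p_threshold, paradox_threshold)


def redundancy_check(
    table: pd.DataFrame,
    biomarkers: list[str] | tuple[str, ...],
    r_cutoff: float = 0.75,
) -> list[tuple[str, str, float]]:
    """Flag biomarker pairs whose |Pearson r| strictly exceeds the cutoff.

    A pair at exactly the cutoff is not flagged.  Returns
    ``(marker_a, marker_b, r)`` tuples; removal is left to the caller
    (convention: drop the member with the weaker CA R-squared).
    """
    if len(biomarkers) < 2:
        raise PanelError("redundancy check needs at least 2 biomarkers")
    flagged = []
    for a, b in combinations(biomarkers, 2):
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        r = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
        if abs(r) > r_cutoff:
            flagged.append((a, b, r))
    return flagged
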