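"""Named biomarker panels.

Built-ins:

* ``kdm8`` — the routine clinical-chemistry octet (creatinine, albumin,
  cholesterol, blood urea nitrogen, systolic and diastolic blood pressure,
  pulse, HbA1c);
* ``kdm7-accord`` — kdm8 without BUN (for datasets that lack it);
* ``kdm8-crp`` — kdm8 with HbA1c replaced by C-reactive protein, for
  analyses where A1c is confounded by the disease under study;
* ``kdm7-nosbp`` — kdm8 without systolic blood pressure;
* ``phage9`` — the nine Phenotypic-Age markers in Levine units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import PanelError
from .simulate import PHAGE_MARKERS

__all__ = ["PanelConfig", "BUILTIN_PANELS", "get_panel"]


@dataclass(frozen=True)
class PanelConfig:
    panel_id: str
    biomarkers: tuple[str, ...]
    units: dict[str, str] = field(default_factory=dict)

    def validate_against(self, table: pd.DataFrame) -> None:
        absent = [b for b in self.biomarkers if b not in table.columns]
        if absent:
            raise PanelError(
                f"panel {self.panel_id!r}: column(s) absent from table: "
                + ", ".join(absent)
            )


_KDM8 = ("creatinine", "albumin", "cholesterol", "bun", "sbp", "dbp", "pulse", "a1c")
_KDM_UNITS = {
    "creatinine": "mg/dL",
    "albumin": "g/dL",
    "cholesterol": "mg/dL",
    "bun": "mg/dL",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "pulse": "/min",
    "a1c": "%",
    "crp": "mg/dL",
}
_PHAGE_UNITS = {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "glucose": "mmol/L",
    "crp": "mg/dL",
    "lymphocyte_pct": "%",
    "mcv": "fL",
    "rdw": "%",
    "alp": "U/L",
    "wbc": "1000 cells/uL",
}

BUILTIN_PANELS: dict[str, PanelConfig] = {
    "kdm8": PanelConfig("kdm8", _KDM8, dict(_KDM_UNITS)),
    "kdm7-accord": PanelConfig(
        "kdm7-accord", tuple(b for b in _KDM8 if b != "bun"), dict(_KDM_UNITS)
    ),
    "kdm8-crp": PanelConfig(
        "kdm8-crp",
        tuple("crp" if b == "a1c" else b for b in _KDM8),
        dict(_KDM_UNITS),
    ),
    "kdm7-nosbp": PanelConfig(
        "kdm7-nosbp", tuple(b for b in _KDM8 if b != "sbp"), dict(_KDM_UNITS)
    ),
    "phage9": PanelConfig("phage9", PHAGE_MARKERS, dict(_PHAGE_UNITS)),
}


def get_panel(panel_id: str, biomarkers: tuple[str, ...] | list[str] | None = None) -> PanelConfig:
    """Look up a built-in panel, or build a custom one from explicit markers."""
    if biomarkers is not None:
        return PanelConfig(panel_id, tuple(biomarkers))
    try:
        return BUILTIN_PANELS[panel_id]
    except KeyError:
        raise PanelError(
            f"unknown panel {panel_id!r}; built-ins: {sorted(BUILTIN_PANELS)}"
        ) from None
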