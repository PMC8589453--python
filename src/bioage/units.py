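"""Exact scalar unit conversions for the Phenotypic-Age marker set.

The supported pairs are the ones needed to move US survey units into the
formula's native units: albumin g/dL -> g/L (x10), creatinine
mg/dL -> umol/L (x88.42, creatinine molar mass 113.12 g/mol), glucose
mg/dL -> mmol/L (/18.016, glucose molar mass 180.16 g/mol).  Inverses are
included; round trips return the input to machine precision.
"""

from __future__ import annotations

import numpy as np

from .errors import UnitError

__all__ = ["unit_convert", "SUPPORTED_CONVERSIONS"]

_FACTORS: dict[tuple[str, str], float] = {
    ("g/dL", "g/L"): 10.0,
    ("mg/dL", "umol/L"): 88.42,
    ("mg/dL", "mmol/L"): 1.0 / 18.016,
}
# add inverses
_FACTORS.update({(b, a): 1.0 / f for (a, b), f in list(_FACTORS.items())})

SUPPORTED_CONVERSIONS = tuple(sorted(_FACTORS))


def unit_convert(value, from_unit: str, to_unit: str):
    """Convert a scalar or array between supported biomarker units."""
    if from_unit == to_unit:
        return value
    try:
        factor = _FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise UnitError(
            f"unsupported conversion {from_unit!r} -> {to_unit!r}; "
            f"supported pairs: {SUPPORTED_CONVERSIONS}"
        ) from None
    return np.multiply(value, factor)
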