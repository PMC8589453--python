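"""Exception hierarchy for the bioage package.

All package errors derive from :class:`BioAgeError`, so callers can catch a
single base class at pipeline boundaries while the library raises specific
subclasses at the point of failure.
"""


class BioAgeError(Exception):
    """Base class for all bioage errors."""


class ConfigurationError(BioAgeError):
    """An invalid configuration value; the message names the field."""


class SchemaError(BioAgeError):
    """A required column is absent or has the wrong type."""


class PanelError(BioAgeError):
    """A biomarker panel is incomplete or inconsistent with the data."""


class FitError(BioAgeError):
    """Model calibration failed (constant column, rank deficiency, ...)."""


class ConvergenceError(FitError):
    """An iterative fit did not converge within its iteration cap."""


class PredictionError(BioAgeError):
    """Prediction requested for subjects the model cannot score."""


class AdjustmentError(BioAgeError):
    """Gender adjustment is impossible (e.g. single-gender input)."""


class DomainError(BioAgeError):
    """A value lies outside the mathematical domain of a transform."""


class StatisticsError(BioAgeError):
    """A statistical comparison was requested on a degenerate sample."""


class StratificationError(BioAgeError):
    """A stratified split cannot be formed (stratum too small)."""


class UnitError(BioAgeError):
    """An unsupported unit conversion pair."""


class PipelineError(BioAgeError):
    """A pipeline stage aborted; the message names the stage."""
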