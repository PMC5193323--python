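"""Exception hierarchy shared across the package."""


class TauDivError(Exception):
    """Base class for all taudiv errors."""


class FormatError(TauDivError):
    """An input file violates the documented tabular dialect or an invariant."""


class DimensionError(TauDivError):
    """Too few tissues (or points) remain for the requested computation."""


class StateError(TauDivError):
    """An operation was applied to data in the wrong state (e.g. double log)."""


class ConfigError(TauDivError):
    """Invalid configuration value or combination."""


class EmptyResultError(TauDivError):
    """A filter or selection removed every record."""


class CalibrationLookupError(TauDivError, LookupError):
    """A node label could not be resolved to an age."""

    def __init__(self, label: str):
        super().__init__(f"node label {label!r} is not present in the age calibration")
        self.label = label


class DegenerateDesignError(TauDivError):
    """The regression design matrix is singular (e.g. all ages identical)."""


class UndefinedCorrelationError(TauDivError):
    """Correlation is undefined because one side has zero variance."""
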