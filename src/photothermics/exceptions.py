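"""Exception and warning hierarchy.

All library errors derive from :class:`PhotothermicsError`; all non-fatal
flags are emitted through the :mod:`warnings` machinery with categories
derived from :class:`PhotothermicsWarning`, so callers can filter or
escalate them uniformly.
"""


class PhotothermicsError(Exception):
    """Base class for all library errors."""


class InvalidInputError(PhotothermicsError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(PhotothermicsError):
    """Too few samples to perform the requested operation."""


class DegenerateFitError(PhotothermicsError):
    """A regression has no information to fit (zero predictor variance)."""


class MassBalanceError(PhotothermicsError):
    """A computed dye mass exceeds what was fed to the experiment."""


class ConfigError(PhotothermicsError):
    """A run configuration failed validation."""


class ParseError(PhotothermicsError):
    """A data file could not be parsed; carries file name and row number."""

    def __init__(self, message: str, path=None, row: int | None = None):
        self.path = str(path) if path is not None else None
        self.row = row
        loc = ""
        if self.path is not None:
            loc = f" [{self.path}" + (f", row {row}]" if row is not None else "]")
        super().__init__(message + loc)


class PhotothermicsWarning(UserWarning):
    """Base class for all library warnings."""


class PlateauFallbackWarning(PhotothermicsWarning):
    """Plateau window too short for the k-sample mean; max sample used."""


class EfficiencyBoundsWarning(PhotothermicsWarning):
    """Estimated conversion efficiency lies outside [0, 1]."""


class MassBalanceWarning(PhotothermicsWarning):
    """A computed dye mass was clamped to keep the mass balance physical."""


class CalibrationRangeWarning(PhotothermicsWarning):
    """An inverted concentration falls outside the calibrated range."""


class MonotonicityWarning(PhotothermicsWarning):
    """A quantity expected to be monotone (e.g. ΔT vs power) is not."""


class ProliferationWarning(PhotothermicsWarning):
    """Cell viability above 120% of control; likely proliferation or error."""
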