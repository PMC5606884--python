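"""Exception hierarchy for aposignal.

Every module raises subclasses of :class:`AposignalError` so callers can
distinguish bad input data (validation) from degenerate scientific cases
(e.g. an all-zero stimulus has no defined quantum catch).
"""


class AposignalError(Exception):
    """Base class for all package errors."""


class SpectrumFormatError(AposignalError):
    """Spectral table is malformed (missing wavelength column, no data columns)."""


class ValidationError(AposignalError):
    """Input violates a domain invariant (non-monotone wavelengths, negative values, ...)."""


class ExtrapolationError(AposignalError):
    """Requested wavelength grid extends beyond the measured range."""


class DegenerateStimulusError(AposignalError):
    """A stimulus yields a non-positive quantum catch; receptor signals undefined."""


class EmptyPatternError(AposignalError):
    """No foreground contour survives extraction/filtering."""


class NoDataError(AposignalError):
    """A summary was requested over an empty record subset."""


class SeparationError(AposignalError):
    """Complete separation in a binomial fit; names the offending term."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(message or f"complete separation detected for term {term!r}")


class ConvergenceError(AposignalError):
    """Iterative fit failed to converge."""


class AnchorError(AposignalError):
    """Dose series lacks the 0% or 100% mortality anchor required by the estimator."""


class SpacingError(AposignalError):
    """Dose series is not a geometric progression."""


class PlacementError(AposignalError):
    """Could not place synthetic shapes without overlap."""


class ConfigError(AposignalError):
    """Invalid simulation configuration."""
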