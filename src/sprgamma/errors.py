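"""Exception hierarchy.

Every error raised by the package derives from :class:`SprGammaError` so
callers (and the CLI) can map failure classes to exit codes.
"""


class SprGammaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SprGammaError):
    """Invalid layer stack, run configuration, or parameter set."""


class DomainError(SprGammaError, ValueError):
    """An input value outside the physically meaningful domain."""


class FormatError(SprGammaError):
    """A data file that cannot be parsed or fails validation."""


class FeatureNotFoundError(SprGammaError):
    """No TIR edge / SPR minimum found in the requested window."""


class NoTIRError(DomainError):
    """Total internal reflection impossible (bulk index >= prism index)."""


class FitNonConvergedError(SprGammaError):
    """Optimizer exhausted its iteration budget without converging."""


class IdentifiabilityError(SprGammaError):
    """Requested free parameters cannot be decoupled by the data."""


class CalibrationError(SprGammaError):
    """Degenerate calibration input (e.g. no solution points with x > 0)."""


class InversionError(SprGammaError):
    """Permittivity-to-composition inversion has no bracketed root."""
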