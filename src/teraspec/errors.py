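"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: validation errors -> 2, data-format
errors -> 3, numerical-domain errors -> 4.
"""


class TeraspecError(Exception):
    """Base class for all teraspec errors."""

    exit_code = 1


class ValidationError(TeraspecError, ValueError):
    """Invalid parameter, geometry, or configuration value."""

    exit_code = 2


class FormatError(TeraspecError, ValueError):
    """Malformed input file (non-numeric rows, non-uniform time axis...)."""

    exit_code = 3


class NumericalDomainError(TeraspecError, ArithmeticError):
    """Computation left its numerical domain (empty band, zero reference...)."""

    exit_code = 4


class DegenerateMediumError(NumericalDomainError):
    """Material model yields a non-propagating medium (Re n ~ 0)."""


class EmptyBandError(NumericalDomainError):
    """No frequency interval clears the dynamic-range floor."""


class IncompatibleSpectraError(ValidationError):
    """Two spectra do not share a frequency grid."""


class InsufficientDataError(ValidationError):
    """Too few samples / grid points / series points for the operation."""
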