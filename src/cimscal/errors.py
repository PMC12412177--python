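"""Exception and warning hierarchy.

Input/format problems and model-fit problems are kept in separate branches
so the command-line layer can map them onto distinct exit codes (2 and 3).
"""


class CimscalError(Exception):
    """Base class for all package errors."""


class InputError(CimscalError):
    """Problems with user-supplied files or values (CLI exit code 2)."""


class FormatError(InputError):
    """A file does not match the expected layout (missing sheet, header, key)."""


class ParseError(FormatError):
    """A cell or field could not be parsed; the message names the location."""


class ValidationError(InputError):
    """A value violates a domain invariant (negative CCS, charge 0, ...)."""


class ModelError(CimscalError):
    """Problems arising while fitting a model (CLI exit code 3)."""


class FitError(ModelError):
    """Nonlinear or linear fit failed on degenerate data."""


class InsufficientDataError(ModelError):
    """Fewer usable points/calibrants than the configured minimum."""


class RankDeficiencyError(ModelError):
    """Regression design has no spread (e.g. all points at the same pass count)."""


class AmbiguousPassCountWarning(UserWarning):
    """Arrival-time ratio falls near a half-integer pass count."""


class MinPassesWarning(UserWarning):
    """An analyte never reaches the configured minimum number of passes."""


class ExtrapolationWarning(UserWarning):
    """Predicted drift value lies well outside the calibrant drift range."""


class BypassToleranceWarning(UserWarning):
    """Bypass trace separation time deviates from the nominal 0.01 ms."""
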