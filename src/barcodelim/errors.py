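"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`BarcodelimError`
so that callers (and the CLI) can map failures to a stable error class.
"""


class BarcodelimError(Exception):
    """Base class for all package errors."""


class FormatError(BarcodelimError):
    """Malformed input file or illegal character."""


class AlignmentError(BarcodelimError):
    """Sequences that should be aligned are not (e.g. ragged rows)."""


class ValidationError(BarcodelimError):
    """Inputs are individually well-formed but mutually inconsistent."""


class ContractViolation(BarcodelimError):
    """A documented precondition of an operation was violated."""


class UndefinedDistanceError(BarcodelimError):
    """No alignment columns survive pairwise deletion for a pair."""


class SaturationError(BarcodelimError):
    """K2P distance undefined: observed divergence beyond the model's range."""


class RootingError(BarcodelimError):
    """The requested outgroup does not correspond to a single edge."""


class ScenarioError(BarcodelimError):
    """A simulation scenario is internally inconsistent."""


class DegenerateCalibrationError(BarcodelimError):
    """Calibration node has zero height; ages cannot be scaled."""
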