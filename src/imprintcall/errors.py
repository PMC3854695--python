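"""Exception hierarchy shared by all pipeline stages.

Each class maps to a distinct non-zero exit code in the command-line
interface, so shell callers can distinguish usage mistakes from bad
configuration, unreadable inputs, and contract violations.
"""


class ImprintError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class ConfigError(ImprintError):
    """Invalid configuration: out-of-range threshold, bad proportions, ..."""

    exit_code = 3


class LoadError(ImprintError):
    """An input file could not be loaded or cross-referenced."""

    exit_code = 4


class ParseError(LoadError):
    """A malformed value inside an otherwise readable file."""


class ContractError(ImprintError):
    """A precondition of an operation was violated by its caller."""

    exit_code = 5


class OrientationError(ContractError):
    """Accession labels of a count/signal record do not match the sample's parents."""


class SignalError(ContractError):
    """A chromatogram signal is unusable (e.g. amplified but both peaks zero)."""


class FitError(ContractError):
    """A calibration fit is impossible (too few points, degenerate abscissa)."""


class ValidationError(ContractError):
    """A validation step received an empty or unusable control set."""
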