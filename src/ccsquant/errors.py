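"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: input/format problems -> 2,
parameter/configuration problems -> 3, computation failures -> 4.
"""


class CcsError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class FormatError(CcsError):
    """A file does not conform to the expected dialect/format."""

    exit_code = 2


class InputError(CcsError):
    """An input file is missing, unreadable or truncated."""

    exit_code = 2


class ParameterError(CcsError):
    """An argument violates an operation's preconditions."""

    exit_code = 3


class ConfigurationError(CcsError):
    """A run configuration is inconsistent or incomplete."""

    exit_code = 3


class ComputationError(CcsError):
    """A numerically valid input led to an undefined computation."""

    exit_code = 4
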