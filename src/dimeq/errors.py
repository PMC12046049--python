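"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (usage/input/numerical), so
library code should raise the most specific class that applies.
"""


class DimeqError(Exception):
    """Base class for all package errors."""


class ValidationError(DimeqError, ValueError):
    """Invalid argument values (negative concentrations, malformed tables...)."""


class InputError(DimeqError, OSError):
    """Missing or unreadable input files / malformed on-disk formats."""


class NumericalError(DimeqError, RuntimeError):
    """A numerical routine failed to converge or produced a non-finite result."""
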