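"""Exception hierarchy.

Exit-code mapping used by the CLI: DataError -> 1, ConfigurationError -> 2.
"""


class HippodtiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HippodtiError):
    """Invalid configuration: missing boundary labels, bad parameters, non-nested models."""


class DataError(HippodtiError):
    """Invalid data: shape/affine mismatches, non-finite fields, empty parcels."""


class ConvergenceError(HippodtiError):
    """Iterative solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
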