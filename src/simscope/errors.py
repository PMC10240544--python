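"""Exception hierarchy shared across the package."""


class SimscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SimscopeError):
    """A depot / device configuration is invalid or incomplete."""


class ValidationError(SimscopeError):
    """An argument violates a documented precondition."""


class AcquisitionError(SimscopeError):
    """A simulated acquisition could not be performed (e.g. camera disabled)."""


class SoftLimitError(SimscopeError):
    """A requested stage move falls outside the combined axis limits.

    Carries the offending dimension name in ``dimension``.
    """

    def __init__(self, message: str, dimension: str | None = None):
        super().__init__(message)
        self.dimension = dimension


class CompileError(SimscopeError):
    """An experiment specification could not be compiled to an action table."""


class ExecutionError(SimscopeError):
    """An action table referenced a line unknown to the executor."""


class DVFormatError(SimscopeError):
    """A .dv / MRC2014 file failed to parse; ``offset`` is the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset
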