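"""Exception types shared across the package."""


class QubofsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(QubofsError, ValueError):
    """A parameter is outside its documented domain."""


class DataError(QubofsError, ValueError):
    """Input data violates a precondition (shape, range, finiteness)."""


class CapacityError(QubofsError, RuntimeError):
    """A combinatorial guard was exceeded (e.g. exhaustive enumeration size)."""


class EmptyResultError(DataError):
    """A filtering step removed everything."""


class UnavailableMethodError(QubofsError, RuntimeError):
    """A baseline method has no reference implementation in this environment."""
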