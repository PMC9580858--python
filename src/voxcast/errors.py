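"""Exception types shared across the package."""


class VoxcastError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VoxcastError, ValueError):
    """Raised when array inputs violate a precondition (shape, finiteness)."""


class FormatError(VoxcastError, ValueError):
    """Raised on malformed or contradictory file/wire formats.

    The message always names the offending field.
    """


class InvalidParameterError(VoxcastError, ValueError):
    """Raised on out-of-range or inconsistent render/view parameters."""


class ApiError(VoxcastError):
    """HTTP-visible error carrying a status code."""

    def __init__(self, status: int, message: str):
        super().__init__(message)
        self.status = status
        self.message = message
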