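"""Exception hierarchy shared across the package."""


class SomicError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SomicError, ValueError):
    """An argument is outside its declared domain (non-finite, negative, out of range)."""


class SchemaError(SomicError, ValueError):
    """A table or config file violates the expected schema; message names the column/row."""


class NumericalError(SomicError, ArithmeticError):
    """The integration produced a non-finite or negative-mass result; message names the pool."""


class ConvergenceError(SomicError, RuntimeError):
    """Spin-up failed to reach the requested tolerance; carries the last state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
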