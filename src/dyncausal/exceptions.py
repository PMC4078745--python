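"""Exception types shared across the package."""


class DynCausalError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DynCausalError, ValueError):
    """A caller-supplied argument violates an operation precondition."""


class StationarityError(DynCausalError, ValueError):
    """A VAR model is not stationary (spectral radius >= 1 - margin)."""


class NumericalError(DynCausalError, ArithmeticError):
    """A covariance submatrix is ill-conditioned or not positive definite."""


class InferenceError(DynCausalError, RuntimeError):
    """An independence oracle returned answers inconsistent with any pattern."""


class UndefinedRatioError(DynCausalError, ZeroDivisionError):
    """A ratio of Granger measures is undefined (denominator at numerical zero)."""


class ParseError(DynCausalError, ValueError):
    """A graph or model file violates the expected schema.

    ``location`` points at the offending element when known.
    """

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        super().__init__(message if location is None else f"{message} (at {location})")
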