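"""Exception hierarchy for circaphase.

Every error raised by the library derives from :class:`CircaphaseError` so
callers can catch library failures without masking programming errors.
"""


class CircaphaseError(Exception):
    """Base class for all circaphase errors."""


class InvalidAngleError(CircaphaseError, ValueError):
    """A non-finite value was supplied where an angle was required."""


class DegenerateDirectionError(CircaphaseError, ValueError):
    """A Cartesian vector too close to the origin to define a direction."""


class UndefinedStatisticError(CircaphaseError, ValueError):
    """A circular statistic is undefined for the given inputs
    (empty input, zero resultant length, zero denominator...)."""


class ShapeError(CircaphaseError, ValueError):
    """Mismatched lengths or misaligned identifiers."""


class ConfigError(CircaphaseError, ValueError):
    """An invalid configuration value."""


class FitError(CircaphaseError, RuntimeError):
    """Model fitting failed (degenerate design, insufficient samples...)."""


class ConvergenceError(FitError):
    """An iterative solver did not converge within its iteration budget."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class AlignmentError(CircaphaseError, KeyError):
    """Feature or sample identifiers could not be aligned."""


class SamplingError(CircaphaseError, ValueError):
    """A training/validation split cannot be constructed as requested."""


class ProvenanceError(CircaphaseError, ValueError):
    """Objects with incompatible provenance were combined."""


class SchemaError(CircaphaseError, ValueError):
    """A file does not conform to its declared schema."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
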