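"""Exception hierarchy shared across the package."""


class NsfecgError(Exception):
    """Base class for all package errors."""


class ParameterError(NsfecgError, ValueError):
    """A parameter violates its documented invariant; names the field."""


class DegenerateSignalError(NsfecgError, ValueError):
    """A waveform has zero power or is otherwise unusable."""


class ConfigurationError(NsfecgError, ValueError):
    """A configuration object is internally inconsistent."""


class NumericalRankError(NsfecgError, ValueError):
    """A matrix is numerically rank deficient beyond regularization."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class DimensionalityError(NsfecgError, ValueError):
    """Requested more components than the problem supports."""


class DegenerateInputError(NsfecgError, ValueError):
    """An input collapses the problem (e.g. projector equals identity)."""


class InsufficientDataError(NsfecgError, ValueError):
    """Not enough samples/peaks to compute the requested quantity."""


class LabelingError(NsfecgError, RuntimeError):
    """Source labelling failed on every row."""


class DivergenceError(NsfecgError, RuntimeError):
    """An iterative scheme diverged; message names the learning rate."""


class FormatError(NsfecgError, ValueError):
    """A file could not be parsed; message carries file/line context."""


class UnavailableMetricError(NsfecgError, RuntimeError):
    """Metric requires ground truth that is not available."""
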