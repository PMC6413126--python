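"""Exception hierarchy shared across the pipeline."""


class GaitsymError(Exception):
    """Base class for all gaitsym errors."""


class FormatError(GaitsymError):
    """Input file is not in the expected format (e.g. not a 16-bit PNG)."""


class ParameterError(GaitsymError, ValueError):
    """A parameter violates its contract (degenerate box, radius <= 0, ...)."""


class EmptyInputError(GaitsymError):
    """An operation received no usable data (empty mask, no valid normals)."""


class DegenerateFeatureError(GaitsymError):
    """An angle feature is undefined because a projected vector vanished."""

    def __init__(self, message: str, region_pair: str | None = None):
        super().__init__(message)
        self.region_pair = region_pair


class InsufficientDataError(GaitsymError):
    """Too few samples for the requested estimate (e.g. < 2 training runs)."""


class DegenerateWeightsError(GaitsymError):
    """All plane weights are zero; the combined index is undefined."""


class EvaluationError(GaitsymError):
    """The benchmark structure does not support the requested evaluation."""


class ConfigurationError(GaitsymError):
    """A simulator configuration is physically invalid."""
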