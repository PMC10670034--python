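"""Exception hierarchy shared across the package."""


class XWClustError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(XWClustError, ValueError):
    """An array has an invalid or mismatched shape."""


class PlacementError(XWClustError, ValueError):
    """A synthetic shape does not fit inside the image frame."""


class DegenerateDataError(XWClustError, ValueError):
    """Training or clustering input lacks the required structure (e.g. one class)."""


class DomainError(XWClustError, ValueError):
    """A scalar argument lies outside the function's domain."""


class MetricError(XWClustError, ValueError):
    """A cluster-quality metric is undefined for the given labelling."""


class ParameterError(XWClustError, ValueError):
    """An invalid hyperparameter or configuration value."""


class ReductionError(XWClustError, ValueError):
    """Dimensionality reduction request is infeasible for the given matrix."""
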