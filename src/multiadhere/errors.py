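"""Exception hierarchy shared across the package."""


class MultiadhereError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MultiadhereError, ValueError):
    """A configuration or generator parameter violates its contract."""


class ScoringError(MultiadhereError, ValueError):
    """Item-level responses cannot be scored (unknown id, wrong count...)."""


class StandardizationError(MultiadhereError, ValueError):
    """Degenerate variance: a pooled SD needed for standardization is
    undefined or zero."""


class EstimationError(MultiadhereError, RuntimeError):
    """A model fit failed in a way that must not be reported as a result
    (e.g. perfect separation in the attrition logistic regression)."""
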