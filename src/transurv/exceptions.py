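"""Exception and warning types used across the package."""


class TransurvError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(TransurvError, ValueError):
    """A dataset violates the censored-survival data contract."""


class ColumnConfigurationError(TransurvError, KeyError):
    """A named time/event column is missing from the input file."""


class MetricUndefinedError(TransurvError, ValueError):
    """A metric has no comparable pairs (or classes) to evaluate."""


class StratificationUndefinedError(MetricUndefinedError):
    """The positive or negative class at the requested time point is empty."""


class FitError(TransurvError, RuntimeError):
    """A model fit failed (non-convergence, solver failure, bad design)."""


class CalibrationError(TransurvError, RuntimeError):
    """The requested censoring rate is unattainable under the study horizon."""


class UnsupportedOperationError(TransurvError, RuntimeError):
    """Operation not available for this model configuration (e.g. nonlinear kernel weights)."""


class ConvergenceWarning(UserWarning):
    """Optimizer stopped in a degraded state (capped coefficients, loose gap)."""


class SeparationWarning(ConvergenceWarning):
    """Monotone partial likelihood detected; coefficients were capped."""
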