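"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ShProtectError`, so callers can catch one type at the pipeline
boundary. Domain errors (bad concentrations, negative times) are
``ValueError`` subclasses; configuration errors (missing fields, bad
designs) are separate so a pipeline can distinguish "your data are
wrong" from "your setup is wrong".
"""


class ShProtectError(Exception):
    """Base class for all package errors."""


class DomainError(ShProtectError, ValueError):
    """A physical quantity is outside its admissible domain."""


class ConfigurationError(ShProtectError):
    """An object is missing a field or combination required for the task."""


class InsufficientDataError(ShProtectError):
    """Too few usable observations to attempt a fit."""


class EstimationError(ShProtectError):
    """A fit failed to converge or produced an unusable result."""


class DegenerateFitError(EstimationError):
    """The fitted line is incompatible with the model (e.g. nonpositive intercept)."""


class UsageError(ShProtectError):
    """Inputs are individually valid but mutually inconsistent."""


class PipelineError(ShProtectError):
    """A staged pipeline run cannot proceed."""
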