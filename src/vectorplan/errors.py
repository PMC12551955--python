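"""Exception hierarchy shared across the package."""


class VectorPlanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VectorPlanError, ValueError):
    """Invalid user-supplied parameters or configuration."""


class NumericalError(VectorPlanError, RuntimeError):
    """A numerical routine failed to converge or produced invalid output."""


class StabilityError(NumericalError):
    """The explicit discretization went unstable; increase substeps per day."""


class EnvironmentError_(VectorPlanError, RuntimeError):
    """A required external component (e.g. an NLP solver) is unavailable."""
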