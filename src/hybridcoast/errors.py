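"""Exception types shared across the pipeline."""


class HybridCoastError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HybridCoastError, ValueError):
    """A configuration value is missing, unknown, or out of range.

    The message names the offending field.
    """


class ParameterError(HybridCoastError, ValueError):
    """An operation was called with an invalid argument."""


class DependencyError(HybridCoastError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""


class AssignmentError(HybridCoastError, ValueError):
    """A transect or cell could not be assigned to a region/catchment."""
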