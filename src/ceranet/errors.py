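"""Exception hierarchy shared by all ceranet modules."""


class CeranetError(Exception):
    """Base class for all errors raised by ceranet."""


class ParameterError(CeranetError, ValueError):
    """An argument or configuration field is outside its valid range."""


class SizingError(ParameterError):
    """A simulated feature cannot be placed on a chromosome of the requested size."""


class ValidationError(ParameterError):
    """A configuration object failed validation; message lists the offending fields."""


class IncompleteCallsError(CeranetError, ValueError):
    """A candidate transcript is missing a verdict from at least one coding-potential tool."""


class ConstantInputError(ParameterError):
    """Correlation of a constant vector is undefined."""


class InsufficientDataError(ParameterError):
    """Too few observations for the requested statistic (correlations need n >= 3)."""


class DegenerateInputError(ParameterError):
    """Input carries no usable information (e.g. an all-zero count matrix)."""


class EmptyClassError(ParameterError):
    """A summary was explicitly requested for a feature class with no members."""


class AlignmentError(CeranetError, ValueError):
    """Feature or sample identifiers do not line up between two inputs."""


class DependencyError(CeranetError, RuntimeError):
    """A pipeline stage was requested before the stage it depends on has run."""
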