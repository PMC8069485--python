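"""Exception hierarchy shared across the pipeline."""


class PAError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PAError):
    """A configuration field is missing, out of range, or inconsistent."""


class ValidationError(PAError):
    """Input data violate a schema or domain invariant."""


class AlignmentError(ValidationError):
    """A time series is not aligned to the requested epoch/day grid."""


class UndefinedCorrelationError(PAError):
    """A correlation is undefined: fewer than 3 complete pairs or a constant margin."""


class DegenerateBootstrapError(PAError):
    """More than half of the bootstrap replicates had a constant margin."""
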