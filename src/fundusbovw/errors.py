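"""Exception hierarchy shared across the pipeline stages."""


class FundusBovwError(ValueError):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(FundusBovwError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(FundusBovwError):
    """An input array or argument violates a stage precondition."""


class InsufficientDataError(FundusBovwError):
    """Too few samples to perform the requested fit or sampling step."""


class FormatError(FundusBovwError):
    """An on-disk artifact is malformed; the message names the offending field."""


class UndefinedROCError(FundusBovwError):
    """An ROC was requested for a score set with only one class present."""


class ProtocolViolationError(FundusBovwError):
    """The cross-dataset protocol was violated (e.g. train/test overlap)."""


class ConsistencyError(FundusBovwError):
    """Artifacts from mismatched runs (codebook or config hash) were mixed."""
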