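"""Exception hierarchy shared across the pipeline stages."""


class CopialError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CopialError, ValueError):
    """A configuration field holds an invalid value; the message names the field."""


class DomainError(CopialError, ValueError):
    """An operation received an argument outside its mathematical domain."""


class DataCoverageError(CopialError):
    """Required records (years, subregion-period cells) are missing from an input table."""


class InsufficientDataError(CopialError):
    """Too few observations to compute the requested statistic."""


class AlignmentError(CopialError):
    """Inputs that must share a period grid do not."""
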