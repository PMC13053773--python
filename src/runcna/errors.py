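"""Exception hierarchy shared across the pipeline stages."""


class RuncnaError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(RuncnaError, ValueError):
    """A synthetic-data specification violates its invariants."""


class InvalidParameterError(RuncnaError, ValueError):
    """A processing parameter is outside its valid range (e.g. cutoff >= Nyquist)."""


class InsufficientDataError(RuncnaError, ValueError):
    """Not enough valid data to satisfy the operation's contract."""


class OnsetNotFoundError(RuncnaError, ValueError):
    """No sustained force-onset crossing was found within the trace."""


class UndefinedCorrelationError(RuncnaError, ValueError):
    """Correlation undefined (zero variance or fewer than 3 complete pairs)."""


class ConfigError(RuncnaError, ValueError):
    """A study configuration is invalid or references missing columns/files."""
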