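"""Exception hierarchy shared across the pipeline stages."""


class AgemetaError(Exception):
    """Base class for all package errors."""


class FormatError(AgemetaError):
    """A file does not follow the expected layout (missing columns, bad GMT line)."""


class ParseError(AgemetaError):
    """A field could not be parsed; the message names the offending line."""


class EmptyInputError(AgemetaError):
    """A file or table had no usable records."""


class DataError(AgemetaError):
    """Values violate a domain invariant (p-value out of range, missing entries)."""


class MetadataError(AgemetaError):
    """A dataset is referenced without metadata, or metadata is inconsistent."""


class ConfigError(AgemetaError):
    """A configuration value is invalid or infeasible."""


class InsufficientDataError(AgemetaError):
    """Too few datasets, interventions, pairs or terms for the requested statistic."""


class InsufficientOverlapError(InsufficientDataError):
    """Two signatures share fewer genes than the required floor."""
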