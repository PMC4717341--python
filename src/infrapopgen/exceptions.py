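"""Exception hierarchy shared across the package."""


class InfrapopgenError(Exception):
    """Base class for all package errors."""


class AlignmentError(InfrapopgenError):
    """Malformed alignment: ragged lengths, empty input, zero-length sites."""


class DuplicateIdError(InfrapopgenError):
    """Sample identifiers are not unique."""


class SchemaError(InfrapopgenError):
    """A required column is missing from a metadata or loads table."""


class ConfigurationError(InfrapopgenError):
    """Invalid configuration value (e.g. non-positive infrapopulation size)."""


class InsufficientDataError(InfrapopgenError):
    """Too few sequences/groups for the requested statistic."""
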