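"""Package exceptions."""


class PvSweetError(Exception):
    """Base class for package errors."""


class ConfigurationError(PvSweetError):
    """A configuration value is out of range or inconsistent."""


class SchemaError(PvSweetError):
    """A mandatory column is missing or a table cannot be interpreted."""


class IntegrityError(PvSweetError):
    """Too many malformed rows, or identifiers do not line up."""


class DegenerateDatasetError(PvSweetError):
    """An analytical dataset ended up empty or single-class."""


class InsufficientDataError(PvSweetError):
    """Not enough observations for the requested estimate."""


class MappingError(PvSweetError):
    """An external corpus does not match the canonical schema."""
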