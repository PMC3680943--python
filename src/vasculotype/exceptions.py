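"""Exception hierarchy shared across the package."""


class VasculotypeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VasculotypeError):
    """A file or table does not conform to the expected on-disk format."""


class ValidationError(VasculotypeError):
    """An in-memory object or argument violates a documented precondition."""


class ConfigError(ValidationError):
    """A configuration field is invalid; the message names the field."""
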