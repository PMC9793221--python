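"""Exception hierarchy.

CLI exit-code convention: ConfigurationError -> 2, the data-related
errors (FormatError, IntegrityError, DataError) -> 3.
"""


class SoygsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SoygsError):
    """Invalid parameter or configuration value; message names the field."""


class FormatError(SoygsError):
    """A file could not be parsed under the requested dialect."""


class IntegrityError(SoygsError):
    """Inconsistent data: duplicate IDs, misaligned samples, bad dimensions."""


class DataError(SoygsError):
    """Data valid in form but unusable for the requested operation."""
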