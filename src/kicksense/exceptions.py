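"""Exception hierarchy shared by all kicksense modules."""


class KicksenseError(Exception):
    """Base class for all kicksense errors."""


class SchemaError(KicksenseError):
    """A column-mapping or config schema is missing required entries."""


class FormatError(KicksenseError):
    """An on-disk file violates its declared format or an invariant."""


class EmptyInputError(KicksenseError):
    """An operation received an empty (or too-short) input."""


class ConfigurationError(KicksenseError):
    """A configuration value is invalid or inconsistent."""


class DegenerateInputError(KicksenseError):
    """Input is structurally valid but too small for the operation."""
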