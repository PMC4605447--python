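"""Exception hierarchy for the package."""


class LingoMccError(Exception):
    """Base class for all package-specific errors."""


class SmilesFormatError(LingoMccError):
    """A library line or SMILES token violates the plain-text contract."""


class InvalidLingoError(LingoMccError):
    """A q-gram cannot be packed (wrong length or non-ASCII character)."""


class IncompatibleProfileError(LingoMccError):
    """Two profiles built with different q cannot be compared."""


class ConfigurationError(LingoMccError):
    """An engine/scheduler/synth configuration value is out of range."""
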