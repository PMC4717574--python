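class AssortmateError(Exception):
    """Base class for package errors."""


class ConfigError(AssortmateError):
    """Invalid configuration or parameter value (CLI exit code 2)."""


class DataError(AssortmateError):
    """Inconsistent or unusable input data (CLI exit code 3)."""
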