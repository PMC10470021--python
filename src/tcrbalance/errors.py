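"""Exception types shared across the package."""


class TcrBalanceError(ValueError):
    """Base class for package-specific errors."""


class DomainError(TcrBalanceError):
    """A quantity left the mathematical domain of an operation (e.g. b = 0)."""


class FormatError(TcrBalanceError):
    """An input table is malformed; the message names the offending column."""


class EmptySampleError(TcrBalanceError):
    """A repertoire sample contains no usable clonotypes."""


class ConfigError(TcrBalanceError):
    """A run configuration failed validation."""
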