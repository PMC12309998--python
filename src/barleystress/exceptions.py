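"""Exception and warning types shared across the package."""


class BarleyStressError(Exception):
    """Base class for package errors."""


class FormatError(BarleyStressError):
    """A file does not match the declared layout (missing key columns etc.)."""


class ValidationError(BarleyStressError):
    """A table violates a data-model invariant (negative value, bad label...)."""


class BalanceError(BarleyStressError):
    """An operation that assumes a balanced design received unbalanced cells."""


class SpecError(BarleyStressError):
    """A simulation spec is internally inconsistent."""


class ConfigError(BarleyStressError):
    """A run configuration is invalid or incompatible with the data."""


class PhenomicsWarning(UserWarning):
    """Non-fatal data issues: dropped columns, deficient cells, truncations."""
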