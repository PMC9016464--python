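"""Exception hierarchy shared across the package."""


class FibroscreenError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FibroscreenError, ValueError):
    """An input is outside the mathematical domain of a formula."""


class ValidationError(FibroscreenError, ValueError):
    """A record or row violates an invariant (range, type, consistency)."""


class SchemaError(FibroscreenError, ValueError):
    """A cohort file does not carry the columns the schema requires."""


class ConfigurationError(FibroscreenError, ValueError):
    """An unknown score name, preset, or malformed coefficient config."""


class DegenerateDataError(FibroscreenError, ValueError):
    """An analysis needs both classes / multiple stages and the data has one."""
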