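"""Exception hierarchy shared across the package."""


class FsdError(Exception):
    """Base class for package errors."""


class ConfigError(FsdError):
    """A configuration file or schema is invalid or incomplete."""


class DataError(FsdError):
    """Input data violate a contract (duplicates, out-of-range values)."""


class ContractViolation(FsdError):
    """An operation was called with inputs that break its precondition."""
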