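"""Exception types shared across the package."""


class EbvsError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(EbvsError, ValueError):
    """An argument violates an operation precondition."""


class SchemaError(EbvsError, ValueError):
    """An input file or table does not conform to the expected schema."""


class ConfigurationError(EbvsError, ValueError):
    """A configuration is internally inconsistent or infeasible."""
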