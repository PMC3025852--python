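"""Exception hierarchy for matriline."""


class MatrilineError(Exception):
    """Base class for all package errors."""


class PedigreeStructureError(MatrilineError):
    """The dam-link graph is malformed (e.g. a cycle in the maternal links)."""


class PedigreeReferenceError(MatrilineError):
    """A dam_id points at a missing individual."""


class DomainError(MatrilineError):
    """A value violates a domain invariant (e.g. a male listed as a dam)."""


class UndefinedValueError(MatrilineError):
    """A requested quantity is undefined for the given input (e.g. a sex
    ratio with zero sexed offspring)."""


class ConfigurationError(MatrilineError):
    """Invalid simulation or sampler configuration."""


class SchemaError(MatrilineError):
    """An input file does not conform to the expected column schema."""


class StateConsistencyError(MatrilineError):
    """A ParameterState is missing an effect required by a record."""


class CapabilityError(MatrilineError):
    """The request exceeds what an operation supports (e.g. too many free
    parameters for the quadrature oracle)."""
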