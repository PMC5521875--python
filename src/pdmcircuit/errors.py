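"""Exception types raised across the package."""


class PdmCircuitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PdmCircuitError):
    """A tabular input is missing a required column or header."""


class ValidationError(PdmCircuitError):
    """A value violates a domain invariant (e.g. unknown region token)."""


class ReferentialError(PdmCircuitError):
    """Cross-table reference is broken (e.g. session without metadata)."""


class ParameterError(PdmCircuitError):
    """A function argument is outside its admissible range."""


class InsufficientDataError(PdmCircuitError):
    """Not enough samples/events/units to compute the quantity."""


class DegenerateNullError(PdmCircuitError):
    """A surrogate null distribution has zero spread."""


class UndefinedMetricError(PdmCircuitError):
    """The metric is undefined for this input (e.g. EI of a zero filter)."""
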