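"""Exception hierarchy for the phyletica pipeline."""


class PhyleticaError(Exception):
    """Base class for all package-specific errors."""


class MatrixParseError(PhyleticaError):
    """A trait-matrix cell or header could not be parsed."""


class SchemeMismatchError(PhyleticaError):
    """A trait identifier does not match the declared identifier scheme."""


class ValidationError(PhyleticaError):
    """An input table violates a schema or value constraint."""


class ConfigurationError(PhyleticaError):
    """Inconsistent or incomplete run configuration."""


class StructuralError(PhyleticaError):
    """An ontology DAG or trait tree violates a structural requirement."""


class NotApplicableError(PhyleticaError):
    """An operation was requested on an input outside its domain."""


class ConsistencyError(PhyleticaError):
    """A cross-module conservation identity failed to hold."""
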