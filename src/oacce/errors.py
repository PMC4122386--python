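"""Exception hierarchy for the oacce model."""


class OacceError(Exception):
    """Base class for all package errors."""


class SchemaError(OacceError):
    """A configuration file does not match the documented schema
    (missing key, wrong type, unparseable file)."""


class InvalidParameterError(OacceError):
    """A structurally valid parameter set violates a model invariant.

    Carries the validation report so callers can inspect every violated
    field path.
    """

    def __init__(self, report):
        self.report = report
        super().__init__("parameter validation failed:\n" + str(report))


class DomainError(OacceError):
    """An operation received an argument outside its mathematical domain
    (negative rate, split not summing to one, ...)."""


class DataError(OacceError):
    """A lookup table (life table, inflation index, per-score rates) does
    not cover a required key."""


class ConfigurationError(OacceError):
    """A policy/method tag or parameter id could not be resolved."""


class ModelLogicError(OacceError):
    """An operation was invoked on a state in which it is undefined
    (e.g. a second recurrent stroke)."""
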