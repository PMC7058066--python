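"""Exception hierarchy for the nitrogen-flow toolkit."""


class NFlowError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(NFlowError):
    """A table, registry or definition references something that does not resolve."""


class UnknownCompartmentError(ConfigurationError):
    """A flux record names a compartment id absent from the registry."""


class DuplicateFluxError(ConfigurationError):
    """Two flux records share the (source, target, year, label) key."""


class UnitError(NFlowError):
    """An activity x parameter product does not reduce to Gg N under the conversion table."""


class DomainError(NFlowError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class ConsistencyError(NFlowError):
    """Internally inconsistent quantities (e.g. a part exceeding its whole)."""


class SingularityError(NFlowError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, predictors: tuple[str, ...] = ()):
        super().__init__(message)
        self.predictors = predictors
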