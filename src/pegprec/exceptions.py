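"""Exception hierarchy for pegprec."""


class PegPrecError(Exception):
    """Base class for all pegprec errors."""


class DomainError(PegPrecError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InvalidParameterError(PegPrecError, ValueError):
    """A parameter set violates the model's invariants or overflows."""


class SolverError(PegPrecError, RuntimeError):
    """The equilibrium root solve failed; carries a diagnostic payload."""

    def __init__(self, message, payload=None):
        super().__init__(message)
        self.payload = dict(payload or {})


class IdentifiabilityError(PegPrecError, ValueError):
    """The dataset cannot constrain the model parameters."""


class ConfigError(PegPrecError, ValueError):
    """Invalid configuration or dataset layout for the requested operation."""
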