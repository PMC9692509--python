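"""Exception hierarchy for nasomag.

Every error raised by the package derives from :class:`NasomagError` so that
callers can catch the whole family with one clause.
"""


class NasomagError(Exception):
    """Base class for all nasomag errors."""


class ResolutionError(NasomagError):
    """Grid spacing too coarse to resolve a geometric feature."""


class DomainError(NasomagError):
    """A query point lies outside the geometric domain."""


class ConfigurationError(NasomagError):
    """Invalid or inconsistent run configuration."""


class ParameterError(NasomagError):
    """A physical parameter is outside its admissible range."""


class STLReadError(NasomagError):
    """An STL surface file could not be parsed."""


class SolverError(NasomagError):
    """The flow solver failed to converge."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class SamplingError(NasomagError):
    """A field was sampled outside the fluid region."""


class IntegrationError(NasomagError):
    """Particle integration produced an invalid state."""

    def __init__(self, message, particle_id=None, time=None, position=None):
        super().__init__(message)
        self.particle_id = particle_id
        self.time = time
        self.position = position


class IncompleteRunError(NasomagError):
    """An analysis was requested on non-terminal particle states."""


class AccountingError(NasomagError):
    """A terminal particle position could not be mapped to a boundary region."""
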