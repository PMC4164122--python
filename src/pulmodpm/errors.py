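"""Exception hierarchy for pulmodpm."""


class PulmoError(Exception):
    """Base class for all pulmodpm errors."""


class InvalidParameterError(PulmoError, ValueError):
    """A parameter is outside its physically meaningful range."""


class DomainError(PulmoError, ValueError):
    """A function argument is outside the domain of validity."""


class InvalidStateError(PulmoError, ValueError):
    """A model state is inconsistent (negative concentration, flow mismatch...)."""


class ConfigError(PulmoError, ValueError):
    """A scenario configuration failed validation."""


class SolverError(PulmoError, RuntimeError):
    """The time-stepping solver produced an unusable state."""


class ConvergenceError(PulmoError, RuntimeError):
    """An iterative procedure did not converge within its budget."""


class FitError(PulmoError, RuntimeError):
    """A calibration fit failed or was given degenerate data."""
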