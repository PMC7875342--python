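"""Exception hierarchy."""


class GliofrontError(Exception):
    """Base class for all package-specific errors."""


class FieldError(GliofrontError, ValueError):
    """A field array violates an invariant (negativity, shape mismatch, ...)."""


class ParameterError(GliofrontError, ValueError):
    """A model or solver parameter is outside its admissible range."""


class ConfigError(GliofrontError, ValueError):
    """A configuration file or scenario specification is invalid."""


class SolverError(GliofrontError, RuntimeError):
    """Time stepping failed (singular system, CFL violation, non-finite state)."""
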