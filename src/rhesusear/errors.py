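"""Exception hierarchy for rhesusear."""


class RhesusEarError(Exception):
    """Base class for all rhesusear errors."""


class ConfigurationError(RhesusEarError, ValueError):
    """A configuration value is missing, malformed or out of range."""


class GeometryError(RhesusEarError, ValueError):
    """A geometric construction is physically inconsistent (e.g. an
    electrode larger than the duct it occupies)."""


class DomainError(RhesusEarError, ValueError):
    """A coordinate or frequency lies outside the model's domain."""


class SolverError(RhesusEarError, RuntimeError):
    """The harmonic linear system could not be solved reliably."""


class CalibrationError(RhesusEarError, RuntimeError):
    """The phenomenological calibration failed (non-finite objective)."""
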