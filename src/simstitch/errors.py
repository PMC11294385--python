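"""Exception hierarchy for the toolkit."""


class SimStitchError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(SimStitchError):
    """Invalid panel/simulation configuration (e.g. unknown molecule name)."""


class DomainError(SimStitchError, ValueError):
    """An argument is outside the physically meaningful domain."""


class PlanningError(SimStitchError):
    """Window planning cannot proceed (e.g. overlap >= width)."""


class ConsistencyError(SimStitchError):
    """Data structures disagree (segment window not in plan, record outside window)."""


class FormatError(SimStitchError):
    """A file does not conform to the canonical interchange format."""


class FitError(SimStitchError):
    """Nonlinear fit failed; carries the best iterate and its residual."""

    def __init__(self, message, best=None, residual=None):
        super().__init__(message)
        self.best = best
        self.residual = residual
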