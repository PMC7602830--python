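"""Exception hierarchy shared across the pipeline."""


class VariventError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VariventError, ValueError):
    """A function argument violates its documented precondition."""


class FitFailureError(VariventError, RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class UndefinedResultError(VariventError, ValueError):
    """The requested quantity is undefined for this input (e.g. zero baseline)."""


class TransformInfeasibleError(VariventError, ValueError):
    """A log-transform was requested for data containing non-positive values."""


class SingularDesignError(VariventError, ValueError):
    """The mixed-model design matrix has an empty group-by-time cell."""


class StageError(VariventError, RuntimeError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
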