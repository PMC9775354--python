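"""Exception hierarchy shared by all bryoflux modules."""


class BryofluxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BryofluxError, ValueError):
    """Input violates a precondition (sign, range, shape or ordering)."""


class SignConventionError(InvalidInputError):
    """A respiration magnitude was negative or a flux had the wrong sign."""


class DegreesOfFreedomError(BryofluxError, ValueError):
    """Too few observations to identify the model parameters."""


class ConvergenceError(BryofluxError, RuntimeError):
    """Optimizer failed on every start; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NoCompensationPointError(BryofluxError, ValueError):
    """The fitted curve never crosses zero (rd >= gross asymptote)."""


class UnreachableLevelError(BryofluxError, ValueError):
    """The requested saturation fraction is at or above the asymptote."""


class NoOptimumError(BryofluxError, ValueError):
    """The fitted temperature polynomial has no interior maximum."""


class UndefinedCUEError(BryofluxError, ZeroDivisionError):
    """Carbon use efficiency is undefined because NP + DR = 0."""


class AlignmentError(BryofluxError, ValueError):
    """Two logger series share no timestamps."""


class DegenerateDesignError(BryofluxError, ValueError):
    """A regression design matrix is singular or has a constant covariate."""


class PipelineError(BryofluxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending sample."""

    def __init__(self, stage, message, sample_id=None):
        super().__init__(f"[{stage}] {message}" + (f" (sample {sample_id})" if sample_id else ""))
        self.stage = stage
        self.sample_id = sample_id
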