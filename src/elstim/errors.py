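"""Exception hierarchy for the elstim toolkit."""


class ElstimError(Exception):
    """Base class for all elstim errors."""


class InvalidParameterError(ElstimError, ValueError):
    """A parameter violates its documented range (e.g. negative sigma)."""


class DegenerateDesignError(ElstimError, ValueError):
    """The stimulus design is unusable (e.g. every electrode masked)."""


class CalibrationError(ElstimError, RuntimeError):
    """The sigma-calibration sigmoid fit failed to converge."""


class InsufficientSpikesError(ElstimError, ValueError):
    """Too few spike-eliciting stimuli for the requested analysis."""


class DegenerateResponseError(ElstimError, ValueError):
    """Response vector carries no information (all zero or all one)."""


class DegenerateClusterError(ElstimError, ValueError):
    """Fewer distinct latency values than requested clusters."""


class FitFailureError(ElstimError, RuntimeError):
    """Nonlinear least squares failed after all restarts."""


class InsufficientSupportError(ElstimError, ValueError):
    """Too few well-sampled grid cells to fit a 2-D surface."""


class UndefinedExtentError(ElstimError, ValueError):
    """ERF spatial extent is undefined (all weights zero)."""


class UnreachableThresholdError(ElstimError, ValueError):
    """Stimulation direction cannot drive the cell (w+ . u <= 0)."""


class ValidationError(ElstimError, ValueError):
    """Held-out validation could not be computed."""


class DataLoadError(ElstimError, ValueError):
    """A dataset file failed validation on load."""
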