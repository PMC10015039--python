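"""Exception types shared across the pipeline."""


class PaleoforageError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PaleoforageError, ValueError):
    """A model parameter violates its domain (e.g. p outside [0, 1])."""


class DegenerateModelError(PaleoforageError, ValueError):
    """Inputs make the model undefined (e.g. certain pursuit failure with
    zero pursuit cost, constant predictor, zero-variance feature)."""


class InsufficientDataError(PaleoforageError, ValueError):
    """Too few records to fit or evaluate."""


class ConvergenceError(PaleoforageError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class ExtentError(PaleoforageError, ValueError):
    """A point or age falls outside the supported grid/curve/window."""
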