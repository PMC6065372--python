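"""Exception hierarchy for fluxent."""


class FluxentError(Exception):
    """Base class for all fluxent errors."""


class ModelFormatError(FluxentError):
    """A model or table file could not be parsed, or is internally inconsistent."""


class InfeasibleModelError(FluxentError):
    """The steady-state constraints and flux bounds admit no solution."""


class DegeneratePolytopeError(FluxentError):
    """The feasible set has empty interior (dimension 0 or zero Chebyshev margin)."""


class UnboundedProblemError(FluxentError):
    """An LP objective is unbounded; names the offending reaction when known."""


class NotConvergedError(FluxentError):
    """An iterative computation (ODE steady state, MLE, ladder) did not converge."""


class EffectiveSampleSizeError(FluxentError):
    """Importance reweighting left too few effective samples to be trustworthy."""
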