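"""Exception hierarchy shared across the package."""


class EvapoLLPSError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EvapoLLPSError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class NumericalError(EvapoLLPSError, RuntimeError):
    """A quadrature, root-find or ODE solve failed to converge."""


class DryOutError(EvapoLLPSError, ValueError):
    """More water would be removed than is present; reduce the time step."""


class GeometryError(EvapoLLPSError, ValueError):
    """A tie-line / lever-rule construction is geometrically impossible."""


class FitError(EvapoLLPSError, ValueError):
    """A model fit was rejected (too few points, non-monotone curve, ...)."""
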