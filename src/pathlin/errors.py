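"""Exception hierarchy used across the package."""


class PathlinError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(PathlinError, ValueError):
    """A vector or matrix argument has the wrong shape."""


class ModelValidationError(PathlinError, ValueError):
    """A reaction network violates the model grammar or its invariants."""


class StructuralFormError(PathlinError):
    """A state lacks the guaranteed first-order loss term of the
    -x_k*h1 + h2 + u_k structural form."""


class ConfigurationError(PathlinError, ValueError):
    """Invalid run/generator configuration or undefined request."""


class MetricUndefinedError(PathlinError):
    """An error metric has no defined value (e.g. every component of the
    relative-error denominator was excluded)."""


class NonConvergenceError(PathlinError, RuntimeError):
    """An iterative procedure (integration to steady state, Newton,
    relinearization) failed to converge within its budget."""


class InstabilityError(PathlinError, RuntimeError):
    """A trajectory left the divergence guard — the model is unstable or
    the perturbation drove it into an unstable region."""


class SingularityError(PathlinError, RuntimeError):
    """A linear solve hit a singular or numerically ill-conditioned matrix
    (non-hyperbolic anchor)."""


class IntegrationError(PathlinError, RuntimeError):
    """The ODE integrator reported failure."""
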