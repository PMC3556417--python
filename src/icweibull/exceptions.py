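"""Exception hierarchy for icweibull."""


class ICWeibullError(Exception):
    """Base class for all package errors."""


class IntervalValidationError(ICWeibullError, ValueError):
    """An observation interval violates L >= 0 or L < R."""


class ParseError(ICWeibullError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class NonIdentifiableError(ICWeibullError, ValueError):
    """The dataset cannot identify both Weibull parameters (e.g. all
    observations right-censored, or fewer than two distinct finite
    intervals)."""


class ConvergenceError(ICWeibullError, RuntimeError):
    """The optimizer failed to converge after multistart."""


class CurvatureError(ICWeibullError, RuntimeError):
    """The log-likelihood is not concave (in the relevant direction) at the
    requested expansion point, so the Lindley approximation does not apply."""


class ApproximationError(ICWeibullError, RuntimeError):
    """A Lindley-approximated expectation fell outside the domain of the
    loss-function back-transform (e.g. a non-positive interior of a log)."""


class ImproperPosteriorError(ICWeibullError, RuntimeError):
    """The posterior normalizing constant is not finite and positive."""


class QuadratureError(ICWeibullError, RuntimeError):
    """Numerical quadrature of the posterior failed to reach tolerance."""
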