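"""Lindley-approximation Bayes point estimators for the interval-censored
Weibull model.

The posterior expectation of a smooth function u(alpha, beta) under
independent Gamma priors alpha ~ Gamma(a, b), beta ~ Gamma(c, d) is expanded
about the MLE (theta_hat) as

    E[u | data] ~= u + 1/2 (u11 s11 + u22 s22) + u1 rho1 s11 + u2 rho2 s22
                   + 1/2 (l30 u1 s11^2 + l03 u2 s22^2),

where l20, l30, l02, l03 are second/third partials of the log-likelihood at
the MLE, s11 = (-l20)^(-1), s22 = (-l02)^(-1), and rho1 = (a-1)/alpha - b,
rho2 = (c-1)/beta - d are the log-prior gradients (rho = -1/theta at the
noninformative default a = b = c = d = 0).  This is the diagonal form of the
two-parameter Lindley expansion: cross terms (sigma12, l21, l12) are omitted
by construction; see docs/methods.md.

Loss functions and their Bayes estimators:

    SELF   u = theta            point = E[theta]
    LINEX  u = exp(-c theta)    point = -(1/c) ln E[exp(-c theta)]
    GELF   u = theta^(-k)       point = E[theta^(-k)]^(-1/k)

GELF at k = -1 reduces identically to SELF; LINEX tends to SELF as c -> 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._derivs import interval_log_derivatives
from .data import IntervalDataset
from .exceptions import ApproximationError, CurvatureError
from .mle import FitResult, fit_mle, log_likelihood
from .weibull import WeibullParams

__all__ = [
    "PriorSpec",
    "LossSpec",
    "LindleyTerms",
    "loglik_derivatives",
    "lindley_expectation",
    "bayes_estimate",
]

logger = logging.getLogger(__name__)

_Z95 = 1.96


@dataclass(frozen=True)
class PriorSpec:
    """Gamma hyperparameters: alpha ~ Gamma(a_scale, b_scale), beta ~
    Gamma(a_shape, b_shape).  All zero (the default) gives the improper
    noninformative prior proportional to 1/(alpha beta)."""

    a_scale: float = 0.0
    b_scale: float = 0.0
    a_shape: float = 0.0
    b_shape: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a_scale, self.b_scale, self.a_shape, self.b_shape) < 0:
            raise ValueError("Gamma hyperparameters must be >= 0")

    def rho(self, params: WeibullParams) -> tuple[float, float]:
        """Log-prior gradients (rho1, rho2) at ``params``."""
        return (
            (self.a_scale - 1.0) / params.scale - self.b_scale,
            (self.a_shape - 1.0) / params.shape - self.b_shape,
        )

    def log_density(self, alpha, beta):
        """Unnormalized log prior density (vectorized)."""
        return (
            (self.a_scale - 1.0) * np.log(alpha) - self.b_scale * alpha
            + (self.a_shape - 1.0) * np.log(beta) - self.b_shape * beta
        )


@dataclass(frozen=True)
class LossSpec:
    """Loss family ``self`` | ``linex`` | ``gelf`` with its asymmetry
    parameter (LINEX c or GELF k; must be nonzero, None for SELF)."""

    family: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("self", "linex", "gelf"):
            raise ValueError(f"unknown loss family {self.family!r}")
        if self.family == "self":
            if self.parameter is not None:
                raise ValueError("squared-error loss takes no parameter")
        elif not self.parameter:
            raise ValueError(f"{self.family} loss requires a nonzero parameter")


@dataclass(frozen=True)
class LindleyTerms:
    """Summed log-likelihood derivatives at the expansion point, their
    reciprocal curvatures, and per-observation scratch arrays.

    ``x``/``y`` are the endpoint survival values exp[-(L/alpha)^beta] /
    exp[-(R/alpha)^beta]; ``e``/``f`` the corresponding -(t/alpha)^beta; and
    ``w``/``r_log`` the -ln(t/alpha) factors (0 where undefined at t = 0 or
    t = inf, matching the limits used by the derivatives).
    """

    l20: float
    l30: float
    l02: float
    l03: float
    sigma11: float
    sigma22: float
    x: np.ndarray
    y: np.ndarray
    e: np.ndarray
    f: np.ndarray
    w: np.ndarray
    r_log: np.ndarray


def loglik_derivatives(data: IntervalDataset, at: WeibullParams) -> LindleyTerms:
    """Second and third partials of the log-likelihood at ``at``, summed over
    observations, with right-censored endpoints contributing exactly 0 and
    L = 0 endpoints evaluated at their limits.

    Raises :class:`CurvatureError` when either -l20 or -l02 is not positive
    (the Lindley expansion needs a proper maximum).
    """
    left, right = data.to_arrays()
    d = interval_log_derivatives(left, right, at)
    l20 = float(np.sum(d["laa"]))
    l02 = float(np.sum(d["lbb"]))
    if not (-l20 > 0 and -l02 > 0):
        raise CurvatureError(
            f"log-likelihood not concave at {at}: l20={l20:g}, l02={l02:g}"
        )
    a, b = at.scale, at.shape
    fin_l = (left > 0) & np.isfinite(left)
    fin_r = np.isfinite(right) & (right > 0)
    zl = np.where(fin_l, (np.where(fin_l, left, 1.0) / a) ** b, 0.0)
    zr = np.where(fin_r, (np.where(fin_r, right, 1.0) / a) ** b, 0.0)
    return LindleyTerms(
        l20=l20,
        l30=float(np.sum(d["laaa"])),
        l02=l02,
        l03=float(np.sum(d["lbbb"])),
        sigma11=1.0 / (-l20),
        sigma22=1.0 / (-l02),
        x=np.where(left == 0, 1.0, np.exp(-zl)),
        y=np.where(fin_r, np.exp(-zr), 0.0),
        e=-zl,
        f=-zr,
        w=np.where(fin_l, -np.log(np.where(fin_l, left, 1.0) / a), 0.0),
        r_log=np.where(fin_r, -np.log(np.where(fin_r, right, 1.0) / a), 0.0),
    )


def lindley_expectation(
    data: IntervalDataset,
    prior: PriorSpec,
    u: Callable[[float, float], float],
    u1: Callable[[float, float], float],
    u2: Callable[[float, float], float],
    u11: Callable[[float, float], float],
    u22: Callable[[float, float], float],
    *,
    at: WeibullParams | None = None,
    terms: LindleyTerms | None = None,
) -> float:
    """Diagonal two-parameter Lindley expansion of E[u(alpha, beta) | data]
    about the MLE.

    ``u1, u2`` are the first partials in alpha and beta, ``u11, u22`` the
    second; pass ``at``/``terms`` to reuse a fit and its derivatives.
    """
    if at is None:
        at = fit_mle(data).params
    if terms is None:
        terms = loglik_derivatives(data, at)
    a, b = at.scale, at.shape
    rho1, rho2 = prior.rho(at)
    s11, s22 = terms.sigma11, terms.sigma22
    return float(
        u(a, b)
        + 0.5 * (u11(a, b) * s11 + u22(a, b) * s22)
        + u1(a, b) * rho1 * s11
        + u2(a, b) * rho2 * s22
        + 0.5 * (terms.l30 * u1(a, b) * s11**2 + terms.l03 * u2(a, b) * s22**2)
    )


def _zero(a: float, b: float) -> float:
    return 0.0


def _u_functions(loss: LossSpec, which: str):
    """(u, u1, u2, u11, u22) for estimating one parameter; the other
    parameter's partials are identically zero."""
    if loss.family == "self":
        if which == "scale":
            return (lambda a, b: a), (lambda a, b: 1.0), _zero, _zero, _zero
        return (lambda a, b: b), _zero, (lambda a, b: 1.0), _zero, _zero
    if loss.family == "linex":
        c = loss.parameter
        if which == "scale":
            return (
                (lambda a, b: math.exp(-c * a)),
                (lambda a, b: -c * math.exp(-c * a)),
                _zero,
                (lambda a, b: c * c * math.exp(-c * a)),
                _zero,
            )
        return (
            (lambda a, b: math.exp(-c * b)),
            _zero,
            (lambda a, b: -c * math.exp(-c * b)),
            _zero,
            (lambda a, b: c * c * math.exp(-c * b)),
        )
    k = loss.parameter
    if which == "scale":
        return (
            (lambda a, b: a ** (-k)),
            (lambda a, b: -k * a ** (-k - 1.0)),
            _zero,
            (lambda a, b: k * (k + 1.0) * a ** (-k - 2.0)),
            _zero,
        )
    return (
        (lambda a, b: b ** (-k)),
        _zero,
        (lambda a, b: -k * b ** (-k - 1.0)),
        _zero,
        (lambda a, b: k * (k + 1.0) * b ** (-k - 2.0)),
    )


def _point_estimate(expectation: float, loss: LossSpec, which: str) -> float:
    if loss.family == "self":
        return expectation
    if loss.family == "linex":
        if expectation <= 0:
            raise ApproximationError(
                f"Lindley E[exp(-c {which})] = {expectation:g} <= 0; LINEX "
                "back-transform undefined"
            )
        return -math.log(expectation) / loss.parameter
    if expectation <= 0:
        raise ApproximationError(
            f"Lindley E[{which}^(-k)] = {expectation:g} <= 0; GELF "
            "back-transform undefined"
        )
    return expectation ** (-1.0 / loss.parameter)


def _posterior_sd(data, prior, at, terms, which) -> float:
    """Posterior sd via a second Lindley pass with u = theta^2; falls back to
    sqrt(sigma_ii) when the second-moment route loses positivity."""
    self_loss = LossSpec("self")
    mean = lindley_expectation(data, prior, *_u_functions(self_loss, which),
                               at=at, terms=terms)
    if which == "scale":
        sq = (lambda a, b: a * a), (lambda a, b: 2.0 * a), _zero, (lambda a, b: 2.0), _zero
        sigma = terms.sigma11
    else:
        sq = (lambda a, b: b * b), _zero, (lambda a, b: 2.0 * b), _zero, (lambda a, b: 2.0)
        sigma = terms.sigma22
    second = lindley_expectation(data, prior, *sq, at=at, terms=terms)
    var = second - mean * mean
    if var <= 0:
        logger.warning("second-moment posterior variance non-positive (%g) for "
                       "%s; falling back to sqrt(sigma_ii)", var, which)
        return math.sqrt(sigma)
    return math.sqrt(var)


def bayes_estimate(
    data: IntervalDataset,
    prior: PriorSpec = PriorSpec(),
    loss: LossSpec = LossSpec("self"),
    *,
    mle_result: FitResult | None = None,
    terms: LindleyTerms | None = None,
) -> FitResult:
    """Lindley-approximated Bayes point estimates of both parameters under
    the given loss, with posterior-sd standard errors and 95% credible
    intervals (point +/- 1.96 sd).

    ``mle_result``/``terms`` allow reuse across losses on the same data.
    """
    if mle_result is None:
        mle_result = fit_mle(data)
    at = mle_result.params
    if terms is None:
        terms = loglik_derivatives(data, at)

    est = {}
    for which in ("scale", "shape"):
        e = lindley_expectation(data, prior, *_u_functions(loss, which),
                                at=at, terms=terms)
        est[which] = _point_estimate(e, loss, which)
    params = WeibullParams(est["scale"], est["shape"])
    se_a = _posterior_sd(data, prior, at, terms, "scale")
    se_b = _posterior_sd(data, prior, at, terms, "shape")
    return FitResult(
        params=params,
        se_scale=se_a,
        se_shape=se_b,
        ci_scale=(params.scale - _Z95 * se_a, params.scale + _Z95 * se_a),
        ci_shape=(params.shape - _Z95 * se_b, params.shape + _Z95 * se_b),
        method=f"bayes_{loss.family}",
        loglik=log_likelihood(data, params),
        converged=mle_result.converged,
        loss_parameter=loss.parameter,
        n_obs=len(data),
    )
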