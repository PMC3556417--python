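"""Two-parameter Weibull distribution functions and interval probabilities.

The model is parameterized by a scale ``alpha`` (the characteristic life, in
time units: the 63.2nd percentile) and a dimensionless shape ``beta`` that
governs the hazard trend (``beta < 1`` decreasing, ``beta = 1`` constant,
``beta > 1`` increasing).  The survival function is

    S(t) = exp[-(t / alpha) ** beta],

and the probability that a lifetime falls in an inspection interval ``(L, R]``
is ``S(L) - S(R)``, with ``R = inf`` (right censoring) contributing ``S(L)``.
Everything else in the package is built on these two functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["WeibullParams", "survival", "cdf", "pdf", "interval_probability"]


@dataclass(frozen=True)
class WeibullParams:
    """Weibull scale ``alpha`` (> 0, time units) and shape ``beta`` (> 0)."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be a positive finite real, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be a positive finite real, got {self.shape}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.scale, self.shape)


def survival(t, params: WeibullParams):
    """S(t) = exp[-(t/alpha)^beta]; 1 at t = 0 and exactly 0 at t = +inf.

    Accepts a scalar or array ``t``; negative times raise a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival requires t >= 0")
    with np.errstate(over="ignore"):
        z = np.where(np.isinf(t_arr), np.inf, (t_arr / params.scale) ** params.shape)
        out = np.exp(-z)
    return out if out.ndim else float(out)


def cdf(t, params: WeibullParams):
    """F(t) = 1 - S(t)."""
    return 1.0 - survival(t, params)


def pdf(t, params: WeibullParams):
    """Density f(t) = (beta/alpha) (t/alpha)^(beta-1) exp[-(t/alpha)^beta]."""
    a, b = params.scale, params.shape
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("pdf requires t >= 0")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        out = np.where(
            np.isinf(t_arr),
            0.0,
            (b / a) * (t_arr / a) ** (b - 1.0) * np.exp(-((t_arr / a) ** b)),
        )
    # At t=0 the density is 0 for beta>1, beta/alpha for beta=1, +inf for beta<1.
    return out if out.ndim else float(out)


def interval_probability(left: float, right: float, params: WeibullParams) -> float:
    """P(L < T <= R) = S(L) - S(R) for an inspection interval ``(L, R]``.

    ``right`` may be ``inf`` (right censoring).  Strictly positive whenever
    ``L < R`` with finite ``L``.
    """
    if left < 0:
        raise ValueError(f"interval left endpoint must be >= 0, got {left}")
    if not left < right:
        raise ValueError(f"invalid interval: require L < R, got ({left}, {right})")
    return float(survival(left, params) - survival(right, params))
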