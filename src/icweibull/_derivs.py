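"""Analytic derivatives of the interval-censored Weibull log-likelihood.

Every observation contributes ln P with P = S(L) - S(R), where
S(t) = exp(-z) and z = (t/alpha)^beta.  Writing h(t) = S(t), the partial
derivatives of h follow from those of z:

    z_a   = -(beta/alpha) z            z_b   = z w,   w = ln(t/alpha)
    z_aa  =  beta(beta+1)/alpha^2 z    z_bb  = z w^2
    z_aaa = -beta(beta+1)(beta+2)/alpha^3 z
    z_bbb = z w^3                      z_ab  = -(z/alpha)(1 + beta w)

    h_a = -z_a h                h_aa = (z_a^2 - z_aa) h
    h_aaa = (-z_aaa + 3 z_a z_aa - z_a^3) h      (same pattern in beta)
    h_ab = (z_a z_b - z_ab) h

Degenerate endpoints: at t = 0, h = 1 and every derivative is 0 (the limit of
z w^k as t -> 0 is 0 for any beta > 0); at t = +inf, h and all derivatives
are exactly 0.  Both are handled by masking, which also guards the L = 0,
beta < 1 case where naive evaluation of w = ln(t/alpha) produces -inf.

Per-observation derivatives of ln P then come from the quotient rules

    (ln P)''  = P''/P - (P'/P)^2
    (ln P)''' = P'''/P - 3 P'' P'/P^2 + 2 (P'/P)^3.
"""

from __future__ import annotations

import numpy as np

from .weibull import WeibullParams

__all__ = ["endpoint_derivatives", "interval_log_derivatives"]

#: index layout of the derivative stack returned by endpoint_derivatives
H, HA, HAA, HAAA, HB, HBB, HBBB, HAB = range(8)


def endpoint_derivatives(t: np.ndarray, params: WeibullParams) -> np.ndarray:
    """Stack of S(t) and its partials (see module docstring) for an array of
    endpoints ``t`` that may contain 0 and +inf entries.

    Returns an array of shape ``(8, len(t))`` indexed by the module-level
    constants ``H .. HAB``.
    """
    a, b = np.float64(params.scale), np.float64(params.shape)
    t = np.asarray(t, dtype=float)
    out = np.zeros((8, t.size))
    finite = np.isfinite(t) & (t > 0)
    out[H, t == 0] = 1.0  # S(0) = 1, all derivatives 0; t = inf rows stay 0

    tf = t[finite]
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        z = (tf / a) ** b
        h = np.exp(-z)
        w = np.log(tf / a)
        za = -(b / a) * z
        zaa = b * (b + 1.0) / a**2 * z
        zaaa = -b * (b + 1.0) * (b + 2.0) / a**3 * z
        zb = z * w
        zbb = z * w**2
        zbbb = z * w**3
        zab = -(z / a) * (1.0 + b * w)

        out[H, finite] = h
        out[HA, finite] = -za * h
        out[HAA, finite] = (za**2 - zaa) * h
        out[HAAA, finite] = (-zaaa + 3.0 * za * zaa - za**3) * h
        out[HB, finite] = -zb * h
        out[HBB, finite] = (zb**2 - zbb) * h
        out[HBBB, finite] = (-zbbb + 3.0 * zb * zbb - zb**3) * h
        out[HAB, finite] = (za * zb - zab) * h
    # z may overflow to inf at extreme params; exp(-inf) = 0 makes every
    # h-derivative 0 there, but inf * 0 products leave NaNs to clean up.
    np.nan_to_num(out, copy=False, nan=0.0, posinf=0.0, neginf=0.0)
    return out


def interval_log_derivatives(left: np.ndarray, right: np.ndarray,
                             params: WeibullParams) -> dict[str, np.ndarray]:
    """Per-observation derivatives of ln P(L, R] up to third order in each
    parameter (plus the mixed second derivative).

    Returns a dict with keys ``p`` (the interval probabilities) and
    ``la, lb, laa, lbb, laaa, lbbb, lab`` (per-observation derivative
    arrays).  Requires every interval probability to be positive.
    """
    dl = endpoint_derivatives(left, params)
    dr = endpoint_derivatives(right, params)
    d = dl - dr  # P and its derivatives, columns = observations
    p = d[H]
    if np.any(p <= 0):
        bad = int(np.argmax(p <= 0))
        raise FloatingPointError(
            f"interval probability underflowed to {p[bad]} for observation "
            f"({left[bad]}, {right[bad]}) at params {params}"
        )
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        ra, rb = d[HA] / p, d[HB] / p
        return {
            "p": p,
            "la": ra,
            "lb": rb,
            "laa": d[HAA] / p - ra**2,
            "lbb": d[HBB] / p - rb**2,
            "laaa": d[HAAA] / p - 3.0 * d[HAA] * d[HA] / p**2 + 2.0 * ra**3,
            "lbbb": d[HBBB] / p - 3.0 * d[HBB] * d[HB] / p**2 + 2.0 * rb**3,
            "lab": d[HAB] / p - ra * rb,
        }
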