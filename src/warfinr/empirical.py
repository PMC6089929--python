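"""Empirical sub-models of the warfarin-INR system and their analytic integrals.

Three closed-form pieces together replace the mechanistic coagulation
network for prediction purposes:

1. ``approx_si`` — the proportional approximation of the sensitivity index
   of INR to factor VII, ``SI_VII ~= q * INR / VII``, valid once factor VII
   (the fastest-turning-over vitamin K-dependent factor, half-life ~6 h)
   has reached its new steady state.
2. :class:`LogisticSlope` — a three-parameter logistic for the time course
   of ``dSI_VII/dt`` whose asymptote ``h`` and shift ``g`` depend on the
   reference dose ``D_ref``.
3. :class:`QuadraticMap` — a no-intercept quadratic mapping ``dSI_VII/dt``
   to ``dINR/dt``, with dose-dependent coefficients ``k < 0`` and ``m > 0``.

The definite integrals of the logistic and its square have closed forms;
they are implemented here in overflow-safe form (stable ``ln(1+e^x)`` and
sigmoid branches, valid for arguments up to roughly +-700) and are validated
against adaptive quadrature in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit  # numerically stable logistic sigmoid

from .errors import DomainError
from .params import PUBLISHED, PublishedParameters

__all__ = [
    "LogisticSlope",
    "QuadraticMap",
    "approx_si",
    "logistic_slope_at",
    "integral_slope",
    "integral_slope_squared",
    "quadratic_map_apply",
]


def _log1pexp(x):
    """ln(1 + e^x) via the stable branch: x + ln(1+e^(-x)) for large x."""
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class LogisticSlope:
    """Dose-dependent logistic model for dSI_VII/dt over time.

    ``slope(t) = h / (1 + exp(p * (t - g)))`` with ``h = a0 + a1*dref``
    (upper asymptote, per day) and ``g = b0 + b1*ln(dref)`` (horizontal
    shift, days). Defined only for ``dref > 0`` — ``g`` involves the log of
    the dose.
    """

    h: float
    g: float
    p: float
    dref: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise DomainError(f"logistic asymptote h must be positive, got {self.h}")
        if self.p <= 0:
            raise DomainError(f"logistic shape p must be positive, got {self.p}")

    @classmethod
    def from_dref(
        cls, dref: float, params: PublishedParameters = PUBLISHED
    ) -> "LogisticSlope":
        if dref <= 0:
            raise DomainError(f"reference dose must be positive, got {dref}")
        return cls(
            h=params.a0 + params.a1 * dref,
            g=params.b0 + params.b1 * np.log(dref),
            p=params.p,
            dref=dref,
        )


@dataclass(frozen=True)
class QuadraticMap:
    """Dose-dependent quadratic map from dSI_VII/dt to dINR/dt.

    ``dINR/dt = k*slope^2 + m*slope`` with ``k = -exp(c0 + c1*ln(dref)) < 0``
    and ``m = exp(s0 + s1*ln(dref)) > 0``; no intercept, so a zero SI slope
    implies zero INR change.
    """

    k: float
    m: float
    dref: float

    def __post_init__(self) -> None:
        if self.k >= 0:
            raise DomainError(f"second-order coefficient k must be negative, got {self.k}")
        if self.m <= 0:
            raise DomainError(f"first-order coefficient m must be positive, got {self.m}")

    @classmethod
    def from_dref(
        cls, dref: float, params: PublishedParameters = PUBLISHED
    ) -> "QuadraticMap":
        if dref <= 0:
            raise DomainError(f"reference dose must be positive, got {dref}")
        log_d = np.log(dref)
        return cls(
            k=-np.exp(params.c0 + params.c1 * log_d),
            m=np.exp(params.s0 + params.s1 * log_d),
            dref=dref,
        )


def approx_si(inr, vii, params: PublishedParameters = PUBLISHED):
    """Sensitivity index of INR to factor VII, ``SI_VII = q * INR / VII``.

    Parameters
    ----------
    inr
        INR value(s), dimensionless, > 0.
    vii
        Factor VII activity as % of the pre-treatment baseline, > 0.

    Returns
    -------
    float or ndarray
        SI_VII in units of 1/%; strictly increasing in ``inr`` and strictly
        decreasing in ``vii``.
    """
    inr = np.asarray(inr, dtype=float)
    vii = np.asarray(vii, dtype=float)
    if np.any(inr <= 0):
        raise DomainError("INR must be positive — invalid measurement")
    if np.any(vii <= 0):
        raise DomainError("factor VII (% of baseline) must be positive — invalid measurement")
    out = params.q * inr / vii
    return out.item() if out.ndim == 0 else out


def logistic_slope_at(t, model: LogisticSlope):
    """Evaluate dSI_VII/dt (per day) at time ``t`` (days, >= 0).

    ``h / (1 + exp(p*(t-g)))`` computed through the stable sigmoid; monotone
    non-increasing in ``t`` with value exactly ``h/2`` at ``t = g``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    out = model.h * expit(-model.p * (t - model.g))
    return out.item() if out.ndim == 0 else out


def integral_slope(t_lo: float, t_hi: float, model: LogisticSlope) -> float:
    """Definite integral of the logistic slope over ``[t_lo, t_hi]`` (per %).

    Closed form::

        h * [(t_hi - t_lo) - (1/p) * ln((1 + e^{p(t_hi-g)}) / (1 + e^{p(t_lo-g)}))]

    evaluated with the stable ``ln(1+e^x)`` branch. This is the cumulative
    change in SI_VII between the two times.
    """
    _check_interval(t_lo, t_hi)
    p, g, h = model.p, model.g, model.h
    # (t_hi-t_lo) - (1/p)[ln(1+e^{u_hi}) - ln(1+e^{u_lo})] rewritten via
    # u - ln(1+e^u) = -ln(1+e^{-u}): avoids cancellation deep in the tail
    # where the integral is dominated by tiny exponentials.
    u_lo = p * (t_lo - g)
    u_hi = p * (t_hi - g)
    return float((h / p) * (_log1pexp(-u_lo) - _log1pexp(-u_hi)))


def _sq_antideriv(u):
    """Antiderivative F(u) = u - ln(1+e^u) + 1/(1+e^u) of the squared sigmoid.

    F'(u) = sigma(-u)^2, so (h^2/p) * [F(p(t-g))] integrates the squared
    logistic slope in t. Evaluated as ``1/(1+e^u) - ln(1+e^-u)`` (the exact
    identity u - ln(1+e^u) = -ln(1+e^-u)) so that both terms decay for
    u >> 0 and no large-magnitude cancellation occurs.
    """
    return expit(-u) - _log1pexp(-u)


def integral_slope_squared(t_lo: float, t_hi: float, model: LogisticSlope) -> float:
    """Definite integral of (dSI_VII/dt)^2 over ``[t_lo, t_hi]`` (per %^2/day).

    Closed form ``(h^2/p) * [F(u_hi) - F(u_lo)]`` with ``u = p*(t-g)`` and
    ``F(u) = u - ln(1+e^u) + 1/(1+e^u)``; non-negative, overflow-safe.
    """
    _check_interval(t_lo, t_hi)
    p, g, h = model.p, model.g, model.h
    u_lo = p * (t_lo - g)
    u_hi = p * (t_hi - g)
    value = (h * h / p) * (_sq_antideriv(u_hi) - _sq_antideriv(u_lo))
    # F is non-decreasing; clip the tiny negative round-off at u >> 0.
    return float(max(value, 0.0))


def quadratic_map_apply(slope, qmap: QuadraticMap):
    """Map an SI_VII slope (per day, >= 0) to dINR/dt (per day).

    ``k*slope^2 + m*slope``; zero at zero slope (no-intercept model).
    """
    slope = np.asarray(slope, dtype=float)
    out = qmap.k * slope * slope + qmap.m * slope
    return out.item() if out.ndim == 0 else out


def _check_interval(t_lo: float, t_hi: float) -> None:
    if t_lo < 0:
        raise DomainError(f"t_lo must be non-negative, got {t_lo}")
    if t_hi < t_lo:
        raise DomainError(f"integration interval reversed: t_hi={t_hi} < t_lo={t_lo}")
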