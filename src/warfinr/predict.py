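"""Four-step prediction of time to steady-state INR and steady-state INR.

The clinical workflow takes two timed, paired measurements of INR and
factor VII (% of baseline) drawn after factor VII has equilibrated
(days 3 and 4 are the recommended times) and proceeds:

1. Each pair is converted to a sensitivity index ``SI_VII = q*INR/VII``,
   and their finite difference gives the observed ``dSI_VII/dt``.
2. The reference dose ``D_ref`` — the daily dose at which a *typical*
   patient would show the same slope — is found by inverting the
   dose-dependent logistic model. ``D_ref`` is the individualised measure
   of warfarin sensitivity: ``D_ref > D`` means the patient responds as a
   typical patient on a higher dose would, i.e. is more sensitive.
3. ``t_SS,INR`` is the first time the logistic slope at ``D_ref`` falls to
   the tolerance ``eps_si`` (closed form of the relaxed steady-state
   definition).
4. ``INR_SS`` is the baseline INR plus the analytically integrated
   quadratic map of the slope from 0 to ``t_SS,INR``.

Validity guards: samples in the first two days are rejected (factor VII not
yet at steady state); a non-positive slope has no ``D_ref`` (the logistic
shift involves ``ln(D_ref)``); doses outside 1-13 mg/day or predicted INR
outside 1.4-4.7 are extrapolations beyond the calibration range and are
flagged, not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .empirical import (
    LogisticSlope,
    QuadraticMap,
    approx_si,
    integral_slope,
    integral_slope_squared,
    logistic_slope_at,
)
from .errors import DomainError, InversionError, ValidityError
from .params import PUBLISHED, PublishedParameters

__all__ = [
    "PairedSample",
    "DoseContext",
    "PredictionResult",
    "slope_from_pair",
    "invert_dref",
    "time_to_steady_state",
    "steady_state_inr",
    "predict",
    "dose_for_target_inr",
]

#: Fixed search bracket for the reference-dose inversion, mg/day.
DREF_BRACKET = (0.01, 50.0)

InversionMode = Literal["interval-mean", "midpoint"]


@dataclass(frozen=True)
class PairedSample:
    """One timed, paired observation of INR and factor VII.

    ``t`` is days since warfarin start (or the most recent dose-rate
    change); ``vii`` is factor VII activity as % of the pre-treatment
    baseline (100 = untreated).
    """

    t: float
    inr: float
    vii: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise DomainError(f"sample time must be positive, got {self.t}")
        if self.inr <= 0:
            raise DomainError(f"INR must be positive, got {self.inr}")
        if self.vii <= 0:
            raise DomainError(f"factor VII %% must be positive, got {self.vii}")


@dataclass(frozen=True)
class DoseContext:
    """The given daily dose and (optional) measured baseline INR."""

    dose: float
    inr0: float = PUBLISHED.inr0_default

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise DomainError(f"daily dose must be positive, got {self.dose}")
        if self.inr0 <= 0:
            raise DomainError(f"baseline INR must be positive, got {self.inr0}")


@dataclass(frozen=True)
class PredictionResult:
    """Full output of the four-step workflow, including intermediates."""

    si_t1: float
    si_t2: float
    slope: float  # dSI_VII/dt estimate, per day
    dref: float  # individualised reference dose, mg/day
    t_ss_inr: float  # days
    inr_ss: float
    sensitivity_ratio: float  # dref / given dose
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "si_t1": self.si_t1,
            "si_t2": self.si_t2,
            "slope_per_day": self.slope,
            "dref_mg_day": self.dref,
            "t_ss_inr_days": self.t_ss_inr,
            "inr_ss": self.inr_ss,
            "sensitivity_ratio": self.sensitivity_ratio,
            "warnings": list(self.warnings),
        }


def slope_from_pair(
    s1: PairedSample, s2: PairedSample, params: PublishedParameters = PUBLISHED
) -> float:
    """Finite-difference estimate of dSI_VII/dt from two paired samples.

    Both samples must be at or after the factor VII equilibration threshold
    (default day 2): the proportional SI approximation does not hold during
    the first two days of therapy.
    """
    if s1.t < params.vii_equilibration_days:
        raise ValidityError(
            f"sample at day {s1.t} precedes factor VII equilibration "
            f"(earliest valid day: {params.vii_equilibration_days})"
        )
    if s2.t <= s1.t:
        raise DomainError(
            f"second sample must be later than the first (got t1={s1.t}, t2={s2.t})"
        )
    si1 = approx_si(s1.inr, s1.vii, params)
    si2 = approx_si(s2.inr, s2.vii, params)
    return (si2 - si1) / (s2.t - s1.t)


def _model_slope(dref: float, t1: float, t2: float,
                 params: PublishedParameters, mode: InversionMode) -> float:
    model = LogisticSlope.from_dref(dref, params)
    if mode == "midpoint":
        return logistic_slope_at(0.5 * (t1 + t2), model)
    return integral_slope(t1, t2, model) / (t2 - t1)


def invert_dref(
    slope: float,
    t1: float,
    t2: float,
    params: PublishedParameters = PUBLISHED,
    mode: InversionMode = "interval-mean",
) -> float:
    """Solve for the reference dose whose model slope matches the observation.

    By default the observed finite-difference slope is equated to the
    *interval mean* of the logistic over ``[t1, t2]`` — the quantity a
    finite difference of the integrated model actually measures, which
    makes the noiseless round trip exact. ``mode="midpoint"`` instead
    matches the instantaneous slope at the interval midpoint.

    The root is bracketed in (0.01, 50] mg/day, where the model slope is
    strictly increasing in dose for sampling windows in the valid range.
    """
    if slope <= 0:
        raise InversionError(
            "observed dSI_VII/dt is not positive: the patient is already at or "
            "beyond steady-state INR, or the measurements are invalid "
            "(no reference dose exists for a non-increasing sensitivity index)"
        )
    if t2 <= t1:
        raise DomainError(f"t2 must exceed t1 (got t1={t1}, t2={t2})")
    if t1 < params.vii_equilibration_days:
        raise ValidityError(
            f"sampling window starts at day {t1}, before factor VII "
            f"equilibration (day {params.vii_equilibration_days})"
        )
    lo, hi = DREF_BRACKET
    f = lambda d: _model_slope(d, t1, t2, params, mode) - slope
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise InversionError(
            f"observed slope {slope:.3e}/day lies outside the model range "
            f"[{f_lo + slope:.3e}, {f_hi + slope:.3e}] for doses in "
            f"({lo}, {hi}] mg/day — no reference dose solves the inversion"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


def time_to_steady_state(
    dref: float, params: PublishedParameters = PUBLISHED
) -> float:
    """Time (days) until the SI_VII slope first falls to the tolerance.

    Closed form ``t = g(dref) + (1/p) * ln(h(dref)/eps_si - 1)``, clamped at
    zero when the tolerance is already met at the start of therapy.
    """
    model = LogisticSlope.from_dref(dref, params)
    if model.h <= params.eps_si:
        return 0.0  # slope is below tolerance for all t
    t = model.g + np.log(model.h / params.eps_si - 1.0) / model.p
    return float(max(t, 0.0))


def steady_state_inr(
    dref: float,
    inr0: float | None = None,
    params: PublishedParameters = PUBLISHED,
) -> float:
    """Predicted steady-state INR for a given reference dose.

    ``INR_SS = INR_0 + k(dref) * I2 + m(dref) * I1`` where ``I1`` and
    ``I2`` are the analytic integrals of the logistic slope and its square
    from 0 to ``t_SS,INR``. The anticoagulant increment ``INR_SS - INR_0``
    depends only on ``dref``.
    """
    if inr0 is None:
        inr0 = params.inr0_default
    if inr0 <= 0:
        raise DomainError(f"baseline INR must be positive, got {inr0}")
    model = LogisticSlope.from_dref(dref, params)
    qmap = QuadraticMap.from_dref(dref, params)
    t_ss = time_to_steady_state(dref, params)
    i1 = integral_slope(0.0, t_ss, model)
    i2 = integral_slope_squared(0.0, t_ss, model)
    return float(inr0 + qmap.k * i2 + qmap.m * i1)


def _support_warnings(
    dref: float, inr_ss: float, params: PublishedParameters
) -> list[str]:
    w = []
    lo, hi = params.dref_support
    if not lo <= dref <= hi:
        w.append(
            f"dref_extrapolation: D_ref={dref:.3g} mg/day outside the "
            f"calibrated dose range [{lo:g}, {hi:g}]"
        )
    lo, hi = params.inr_support
    if not lo <= inr_ss <= hi:
        w.append(
            f"inr_extrapolation: predicted INR_SS={inr_ss:.3g} outside the "
            f"calibrated INR range [{lo:g}, {hi:g}]"
        )
    return w


def predict(
    s1: PairedSample,
    s2: PairedSample,
    ctx: DoseContext,
    params: PublishedParameters = PUBLISHED,
    mode: InversionMode = "interval-mean",
) -> PredictionResult:
    """Run the full four-step workflow on one patient's paired samples."""
    si1 = approx_si(s1.inr, s1.vii, params)
    si2 = approx_si(s2.inr, s2.vii, params)
    slope = slope_from_pair(s1, s2, params)
    try:
        dref = invert_dref(slope, s1.t, s2.t, params, mode)
    except InversionError as exc:
        raise InversionError(f"reference-dose inversion: {exc}") from exc
    t_ss = time_to_steady_state(dref, params)
    inr_ss = steady_state_inr(dref, ctx.inr0, params)
    return PredictionResult(
        si_t1=si1,
        si_t2=si2,
        slope=slope,
        dref=dref,
        t_ss_inr=t_ss,
        inr_ss=inr_ss,
        sensitivity_ratio=dref / ctx.dose,
        warnings=tuple(_support_warnings(dref, inr_ss, params)),
    )


def dose_for_target_inr(
    target_inr: float,
    sensitivity_ratio: float,
    inr0: float | None = None,
    params: PublishedParameters = PUBLISHED,
) -> float:
    """Daily dose expected to reach a target steady-state INR.

    Inverts ``steady_state_inr(sensitivity_ratio * D, inr0) = target_inr``
    over the supported reference-dose range. ``sensitivity_ratio`` is the
    patient's ``D_ref/D`` from a previous prediction (1 for a typical
    patient).
    """
    if inr0 is None:
        inr0 = params.inr0_default
    if target_inr <= inr0:
        raise DomainError(
            f"target INR ({target_inr}) must exceed baseline INR ({inr0})"
        )
    if sensitivity_ratio <= 0:
        raise DomainError("sensitivity ratio must be positive")
    d_lo, d_hi = (b / sensitivity_ratio for b in params.dref_support)
    f = lambda d: steady_state_inr(sensitivity_ratio * d, inr0, params) - target_inr
    f_lo, f_hi = f(d_lo), f(d_hi)
    if f_lo > 0 or f_hi < 0:
        raise InversionError(
            f"target INR {target_inr} is unreachable within the supported "
            f"reference-dose range {params.dref_support} "
            f"(achievable INR range: [{f_lo + target_inr:.2f}, {f_hi + target_inr:.2f}])"
        )
    return float(brentq(f, d_lo, d_hi, xtol=1e-10, rtol=8.9e-16))
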