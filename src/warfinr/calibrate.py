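"""Recalibration of the empirical sub-models from time-course data.

The empirical system (proportional SI approximation, dose-dependent
logistic slope family, dose-dependent quadratic map) was originally fitted
to simulations from a mechanistic coagulation-network model. These fitters
reproduce that model-order-reduction step from any supplied set of dense
INR / factor VII time courses, e.g. to recalibrate against prospectively
collected patient data.

All fits are unweighted least squares. Nonlinear fits use bounded,
derivative-based optimisation with a deterministic multi-start schedule;
relative standard errors come from the linearised (Jacobian-based)
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .empirical import approx_si
from .errors import DomainError, FitError
from .params import PUBLISHED, PublishedParameters

__all__ = [
    "TimeCourse",
    "FitResult",
    "derive_slope_series",
    "fit_q",
    "fit_logistic_family",
    "fit_quadratic_family",
]

#: Deterministic multiplicative perturbations applied to the data-driven
#: initial guess (first entry = unperturbed start).
_MULTISTART_FACTORS = (1.0, 0.5, 2.0, 0.25, 4.0)


@dataclass(frozen=True)
class TimeCourse:
    """Dense INR / factor VII time course at one constant dosing rate."""

    dose: float  # mg/day
    times: np.ndarray  # days, strictly increasing
    inr: np.ndarray
    vii: np.ndarray  # % of baseline, > 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        inr = np.asarray(self.inr, dtype=float)
        vii = np.asarray(self.vii, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "inr", inr)
        object.__setattr__(self, "vii", vii)
        if not (len(times) == len(inr) == len(vii)):
            raise DomainError("times, inr and vii must have equal lengths")
        if np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(vii <= 0):
            raise DomainError("factor VII must be positive throughout")
        if self.dose <= 0:
            raise DomainError(f"dose must be positive, got {self.dose}")


@dataclass(frozen=True)
class FitResult:
    """Estimates with Jacobian-based uncertainty and goodness of fit."""

    estimates: dict[str, float]
    rse_pct: dict[str, float]  # relative standard errors, %
    r_squared: float  # adjusted coefficient of determination
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def derive_slope_series(
    tc: TimeCourse, params: PublishedParameters = PUBLISHED
) -> np.ndarray:
    """dSI_VII/dt on the time grid of a time course.

    SI_VII is computed pointwise via the proportional approximation, then
    differentiated with central finite differences on the (possibly
    non-uniform) grid, one-sided at the ends.
    """
    if len(tc.times) < 3:
        raise FitError("need at least 3 time points to differentiate SI_VII")
    si = approx_si(tc.inr, tc.vii, params)
    edge_order = 2 if len(tc.times) >= 3 else 1
    return np.gradient(si, tc.times, edge_order=edge_order)


def fit_q(si_true: Sequence[float], ratio: Sequence[float]) -> FitResult:
    """One-parameter regression through the origin: SI_VII = q * (INR/VII).

    ``si_true`` is the directly computed sensitivity index (e.g. the partial
    derivative from a mechanistic model); ``ratio`` the INR-to-factor VII
    ratio at the same times.
    """
    si = np.asarray(si_true, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if si.shape != r.shape or si.ndim != 1:
        raise FitError("si_true and ratio must be 1-D arrays of equal length")
    n = len(si)
    if n < 2:
        raise FitError("at least 2 points are required to estimate q")
    if np.any(r <= 0):
        raise DomainError("INR/VII ratios must be positive")
    denom = float(r @ r)
    if denom == 0.0:
        raise FitError("degenerate ratios: all zero")
    q_hat = float(si @ r) / denom
    resid = si - q_hat * r
    rss = float(resid @ resid)
    # Uncentered total SS: the through-origin model has no intercept, so the
    # conventional centered r^2 is not meaningful here.
    tss = float(si @ si)
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    # sandwich variance, consistent under proportional measurement noise
    var_q = float(np.sum(resid**2 * r**2)) / denom**2 * n / (n - 1)
    rse = 100.0 * np.sqrt(var_q) / abs(q_hat) if q_hat != 0 else np.inf
    return FitResult(
        estimates={"q": q_hat},
        rse_pct={"q": float(rse)},
        r_squared=float(r2_adj),
        residuals=resid,
    )


def _stack_series(
    series: Mapping[float, tuple[Sequence[float], Sequence[float]]],
    min_points: int,
    what: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten {dose: (x, y)} into aligned dose/x/y arrays with validation."""
    if len(series) < 2:
        raise FitError(
            f"{what}: at least 2 dose levels are required "
            "(dose dependency is unidentifiable from one level)"
        )
    doses, xs, ys = [], [], []
    for dose in sorted(series):
        x, y = series[dose]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise FitError(f"{what}: mismatched series lengths at dose {dose}")
        if len(x) < min_points:
            raise FitError(
                f"{what}: need >= {min_points} points per dose, "
                f"got {len(x)} at dose {dose}"
            )
        if dose <= 0:
            raise DomainError(f"{what}: dose must be positive, got {dose}")
        doses.append(np.full(len(x), float(dose)))
        xs.append(x)
        ys.append(y)
    return np.concatenate(doses), np.concatenate(xs), np.concatenate(ys)


def _finish_fit(
    names: Sequence[str],
    result,
    y: np.ndarray,
) -> FitResult:
    """%RSE from the linearised covariance and adjusted r^2 (centered).

    The covariance is the heteroscedasticity-robust (sandwich) form
    ``(J'J)^-1 J' diag(r^2) J (J'J)^-1`` with small-sample scaling
    ``n/(n-k)``: measurement noise in these data is typically proportional
    to the signal, and the plain ``(J'J)^-1 * s^2`` form understates the
    standard errors there.
    """
    theta = result.x
    resid = result.fun
    n, k = len(y), len(theta)
    rss = float(resid @ resid)
    dof = max(n - k, 1)
    jac = result.jac
    try:
        bread = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Jacobian at the optimum: {exc}") from exc
    meat = jac.T @ (resid[:, None] ** 2 * jac)
    cov = bread @ meat @ bread * (n / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore"):
        rse = 100.0 * se / np.abs(theta)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    return FitResult(
        estimates=dict(zip(names, map(float, theta))),
        rse_pct=dict(zip(names, map(float, rse))),
        r_squared=float(r2_adj),
        residuals=resid,
    )


def _multistart_least_squares(residual_fn, theta0: np.ndarray, bounds) -> object:
    """Run the deterministic multi-start schedule; return the best solution."""
    best = None
    lo, hi = bounds
    for factor in _MULTISTART_FACTORS:
        start = np.clip(theta0 * factor, lo, hi)
        try:
            sol = least_squares(
                residual_fn, start, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            "nonlinear least squares failed to converge from every start of "
            f"the multi-start schedule {_MULTISTART_FACTORS}"
        )
    return best


def fit_logistic_family(
    slope_series: Mapping[float, tuple[Sequence[float], Sequence[float]]],
    fix_p: float | None = 0.300,
) -> FitResult:
    """Joint fit of the dose-dependent logistic slope family.

    Parameters
    ----------
    slope_series
        Mapping ``dose -> (times, dSI_VII/dt values)`` with at least two
        dose levels and four time points each.
    fix_p
        Shape parameter held fixed (published value 0.300); pass ``None``
        to estimate ``p`` jointly.

    Fits ``slope(t; D) = (a0 + a1*D) / (1 + exp(p*(t - b0 - b1*ln(D))))``
    by unweighted nonlinear least squares over all doses at once.
    """
    dose, t, y = _stack_series(slope_series, min_points=4, what="logistic family")
    log_dose = np.log(dose)
    p_free = fix_p is None

    def unpack(theta):
        a0, a1, b0, b1 = theta[:4]
        p = theta[4] if p_free else fix_p
        return a0, a1, b0, b1, p

    def residual(theta):
        a0, a1, b0, b1, p = unpack(theta)
        h = a0 + a1 * dose
        g = b0 + b1 * log_dose
        z = np.clip(p * (t - g), -700.0, 700.0)
        return h / (1.0 + np.exp(z)) - y

    theta0 = _logistic_initial_guess(slope_series, fix_p if not p_free else 0.3)
    names = ["a0", "a1", "b0", "b1"]
    n_par = 4
    lo = np.array([-np.inf, 1e-12, -np.inf, 1e-12])
    hi = np.array([np.inf, np.inf, np.inf, np.inf])
    if p_free:
        theta0 = np.append(theta0, 0.3)
        names.append("p")
        n_par = 5
        lo = np.append(lo, 1e-3)
        hi = np.append(hi, 10.0)
    best = _multistart_least_squares(residual, theta0[:n_par], (lo, hi))
    return _finish_fit(names, best, y)


def _logistic_initial_guess(slope_series, p_guess: float) -> np.ndarray:
    """Data-driven starting values for (a0, a1, b0, b1).

    The per-dose maximum slope bounds the asymptote h from below; the time
    at which the slope has fallen to half its maximum anchors the shift g.
    Linear regressions of these per-dose summaries on dose (h) and log-dose
    (g) give the starting coefficients.
    """
    doses = np.array(sorted(slope_series))
    h0, g0 = [], []
    for d in doses:
        t, y = (np.asarray(v, dtype=float) for v in slope_series[d])
        ymax = float(np.max(y))
        h0.append(ymax if ymax > 0 else 1e-6)
        below = np.nonzero(y <= 0.5 * ymax)[0]
        g0.append(float(t[below[0]]) if len(below) else float(t[-1]))
    h0 = np.asarray(h0)
    g0 = np.asarray(g0)
    a1, a0 = np.polyfit(doses, h0, 1)
    b1, b0 = np.polyfit(np.log(doses), g0, 1)
    return np.array([a0, max(a1, 1e-9), b0, max(b1, 1e-9)])


def fit_quadratic_family(
    dinr_dt: Mapping[float, Sequence[float]],
    dsi_dt: Mapping[float, Sequence[float]],
) -> FitResult:
    """Joint fit of the dose-dependent no-intercept quadratic map.

    Parameters
    ----------
    dinr_dt, dsi_dt
        Matched mappings ``dose -> series`` of dINR/dt and dSI_VII/dt.

    Fits ``dINR/dt = -exp(c0 + c1*ln(D)) * x^2 + exp(s0 + s1*ln(D)) * x``
    where ``x = dSI_VII/dt``, jointly across doses.
    """
    if set(dinr_dt) != set(dsi_dt):
        raise FitError("dINR/dt and dSI_VII/dt must cover the same dose levels")
    series = {d: (dsi_dt[d], dinr_dt[d]) for d in dinr_dt}
    dose, x, y = _stack_series(series, min_points=3, what="quadratic family")
    if np.all(x == 0):
        raise FitError("all SI slopes are zero: the quadratic is unidentifiable")
    log_dose = np.log(dose)

    def residual(theta):
        c0, c1, s0, s1 = theta
        k = -np.exp(np.clip(c0 + c1 * log_dose, -700.0, 700.0))
        m = np.exp(np.clip(s0 + s1 * log_dose, -700.0, 700.0))
        return k * x * x + m * x - y

    theta0 = _quadratic_initial_guess(series)
    bounds = (np.full(4, -np.inf), np.full(4, np.inf))
    best = _multistart_least_squares(residual, theta0, bounds)
    return _finish_fit(["c0", "c1", "s0", "s1"], best, y)


def _quadratic_initial_guess(series) -> np.ndarray:
    """Per-dose linear solves for (k, m), then log-log regressions on dose."""
    doses, ks, ms = [], [], []
    for d in sorted(series):
        x, y = (np.asarray(v, dtype=float) for v in series[d])
        design = np.column_stack([x * x, x])
        try:
            (k_d, m_d), *_ = np.linalg.lstsq(design, y, rcond=None)
        except np.linalg.LinAlgError:
            continue
        if k_d < 0 and m_d > 0:
            doses.append(d)
            ks.append(k_d)
            ms.append(m_d)
    if len(doses) < 2:
        # fall back to a neutral start; multi-start will explore around it
        return np.array([1.0, -1.0, 1.0, -0.5])
    doses = np.log(np.asarray(doses))
    c1, c0 = np.polyfit(doses, np.log(-np.asarray(ks)), 1)
    s1, s0 = np.polyfit(doses, np.log(np.asarray(ms)), 1)
    return np.array([c0, c1, s0, s1])
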