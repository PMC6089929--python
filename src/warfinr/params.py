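"""Published parameter set of the empirical warfarin-INR system.

The system couples three empirical sub-models, each calibrated against
simulations from a mechanistic coagulation-network model:

* a proportional approximation of the sensitivity index of INR to factor
  VII, ``SI_VII ~= q * INR / VII``;
* a dose-dependent logistic for the time course of ``dSI_VII/dt`` with
  asymptote ``h(D_ref) = a0 + a1*D_ref`` and shift
  ``g(D_ref) = b0 + b1*ln(D_ref)``;
* a dose-dependent no-intercept quadratic mapping ``dSI_VII/dt`` to
  ``dINR/dt`` with coefficients ``k(D_ref) = -exp(c0 + c1*ln(D_ref))`` and
  ``m(D_ref) = exp(s0 + s1*ln(D_ref))``.

Instances are immutable value objects; the published estimates ship as the
default and can be overridden from a flat YAML/JSON mapping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import DomainError

__all__ = ["PublishedParameters", "PUBLISHED"]


@dataclass(frozen=True)
class PublishedParameters:
    """Immutable container for every printed constant of the empirical system.

    Parameters
    ----------
    q
        Proportionality constant of the SI_VII approximation (dimensionless).
    p
        Logistic shape parameter, per day. Fixed at 0.300 in the published fit.
    a0, a1
        Intercept (per %/day) and dose slope (per %/mg) of the logistic
        asymptote ``h(D_ref)``.
    b0, b1
        Intercept and log-dose slope (both days) of the logistic shift
        ``g(D_ref)``.
    c0, c1
        Log-scale coefficients of the (negative) second-order quadratic
        coefficient ``k(D_ref)``.
    s0, s1
        Log-scale coefficients of the first-order quadratic coefficient
        ``m(D_ref)``.
    eps_si
        Steady-state tolerance on ``dSI_VII/dt``, per day. Steady state is
        declared once the logistic slope falls to this level.
    inr0_default
        Baseline INR assumed when none is measured.
    vii_equilibration_days
        Earliest valid sampling time, days: factor VII is not at its new
        steady state during the first two days of therapy.
    dref_support
        Dose interval (mg/day) covered by the calibration simulations;
        predictions outside it carry an extrapolation warning.
    inr_support
        INR interval covered by the calibration simulations.
    """

    q: float = 0.233
    p: float = 0.300
    a0: float = 0.000392
    a1: float = 0.00108
    b0: float = -1.48
    b1: float = 4.13
    c0: float = 11.9
    c1: float = -2.05
    s0: float = 5.26
    s1: float = -0.672
    eps_si: float = 0.000150
    inr0_default: float = 1.0
    vii_equilibration_days: float = 2.0
    dref_support: tuple[float, float] = (1.0, 13.0)
    inr_support: tuple[float, float] = (1.4, 4.7)

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise DomainError("q must be positive")
        if self.p <= 0:
            raise DomainError("logistic shape p must be positive")
        if self.eps_si <= 0:
            raise DomainError("steady-state tolerance eps_si must be positive")
        if self.a1 <= 0:
            raise DomainError("a1 must be positive (h increases with dose)")
        if self.b1 <= 0:
            raise DomainError("b1 must be positive (g increases with dose)")
        if self.dref_support[0] <= 0 or self.dref_support[1] <= self.dref_support[0]:
            raise DomainError("dref_support must be a positive, increasing interval")
        if self.inr_support[1] <= self.inr_support[0]:
            raise DomainError("inr_support must be an increasing interval")
        if self.vii_equilibration_days < 0:
            raise DomainError("vii_equilibration_days must be non-negative")
        if self.inr0_default <= 0:
            raise DomainError("inr0_default must be positive")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Flat mapping with list-valued support intervals (JSON/YAML safe)."""
        d = dataclasses.asdict(self)
        d["dref_support"] = list(self.dref_support)
        d["inr_support"] = list(self.inr_support)
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "PublishedParameters":
        """Build a parameter set from a flat mapping.

        Unknown keys raise; missing keys fall back to the published default.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(f"unknown parameter field(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("dref_support", "inr_support"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    def replace(self, **overrides: Any) -> "PublishedParameters":
        """Return a copy with the given fields overridden (re-validated)."""
        return self.from_dict({**self.to_dict(), **overrides})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PublishedParameters":
        """Load from YAML or JSON; the format is chosen by the suffix."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise DomainError(f"{path}: expected a flat mapping of parameter fields")
        return cls.from_dict(data)


#: The published parameter set (module-level default used throughout).
PUBLISHED = PublishedParameters()
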