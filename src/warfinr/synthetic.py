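"""Synthetic factor VII / INR data exactly consistent with the empirical system.

The generator stands in for the mechanistic coagulation-network simulator
used to calibrate the empirical models, so every pipeline stage can be
exercised end to end without external data. Construction inverts the
proportional SI approximation:

* the sensitivity index evolves by the published logistic at the patient's
  true reference dose, ``SI(t) = SI(0) + int_0^t slope``;
* factor VII declines mono-exponentially (half-life ~6 h by default) to a
  dose-dependent plateau given by a saturating dose-response;
* INR is then *defined* as ``SI(t) * VII(t) / q``, so noiseless output
  satisfies the identity ``q * INR / VII = SI`` exactly and the prediction
  pipeline recovers the true reference dose to numerical precision.

The VII trajectory shape only sets the realism of INR magnitudes — the
prediction algorithm consumes INR and VII solely through the SI identity.
Optional measurement noise is proportional log-normal, applied last,
independently to INR and VII, with an explicit seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibrate import TimeCourse
from .empirical import LogisticSlope, integral_slope
from .errors import DomainError
from .params import PUBLISHED, PublishedParameters
from .predict import PairedSample

__all__ = ["SyntheticPatient", "SampleSet", "simulate_time_course",
           "make_paired_samples", "make_fixture_suite"]

#: Dose levels used for the calibration fixtures, mg/day.
FIXTURE_DOSES = (1.0, 4.0, 7.0, 10.0, 13.0)


@dataclass(frozen=True)
class SyntheticPatient:
    """Ground truth for one simulated patient.

    ``vii_ss_frac`` (steady-state factor VII as a fraction of baseline) may
    be given directly; by default it follows a saturating sigmoid
    dose-response ``1 - imax * D^n / (D^n + d50^n)`` with maximum fractional
    suppression ``vii_imax``, half-maximal dose ``vii_d50`` (mg/day) and
    Hill exponent ``vii_hill``. The defaults are chosen so that over the
    calibrated 1-13 mg/day range the constructed INR rises monotonically
    from baseline (shallow suppression at low dose, where the sensitivity
    index grows slowly) while staying within clinically plausible magnitude
    at high dose (deep suppression there).
    """

    dref_true: float
    dose_given: float | None = None  # defaults to dref_true (typical patient)
    inr0: float = 1.0
    vii_half_life: float = 0.25  # days (~6 h)
    vii_ss_frac: float | None = None
    vii_imax: float = 0.9
    vii_d50: float = 5.0
    vii_hill: float = 2.0
    noise_cv_inr: float = 0.0
    noise_cv_vii: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dref_true <= 0:
            raise DomainError("dref_true must be positive")
        if self.vii_half_life <= 0:
            raise DomainError("vii_half_life must be positive")
        if self.inr0 <= 0:
            raise DomainError("inr0 must be positive")
        frac = self.plateau_frac
        if not 0 < frac <= 1:
            raise DomainError(f"steady-state VII fraction must be in (0, 1], got {frac}")

    @property
    def dose(self) -> float:
        return self.dose_given if self.dose_given is not None else self.dref_true

    @property
    def plateau_frac(self) -> float:
        """Steady-state factor VII as a fraction of baseline."""
        if self.vii_ss_frac is not None:
            return self.vii_ss_frac
        dn = self.dref_true**self.vii_hill
        return 1.0 - self.vii_imax * dn / (dn + self.vii_d50**self.vii_hill)


@dataclass(frozen=True)
class SampleSet:
    """Paired samples plus the ground truth that generated them."""

    samples: tuple[PairedSample, ...]
    truth: SyntheticPatient
    flags: tuple[str, ...] = ()


def simulate_time_course(
    patient: SyntheticPatient,
    times: Sequence[float],
    params: PublishedParameters = PUBLISHED,
) -> TimeCourse:
    """Simulate (INR, factor VII) on a time grid (days, strictly increasing, > 0)."""
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise DomainError("all simulation times must be positive")
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise DomainError("times must be a strictly increasing 1-D grid")

    frac = patient.plateau_frac
    vii = 100.0 * (frac + (1.0 - frac) * np.exp(-np.log(2.0) * times / patient.vii_half_life))

    model = LogisticSlope.from_dref(patient.dref_true, params)
    si0 = params.q * patient.inr0 / 100.0  # SI at baseline (INR=inr0, VII=100%)
    si = si0 + np.array([integral_slope(0.0, t, model) for t in times])
    inr = si * vii / params.q

    if patient.noise_cv_inr > 0 or patient.noise_cv_vii > 0:
        rng = np.random.default_rng(patient.seed)
        inr = inr * _lognormal_factor(rng, patient.noise_cv_inr, len(times))
        vii = vii * _lognormal_factor(rng, patient.noise_cv_vii, len(times))

    return TimeCourse(dose=patient.dref_true, times=times, inr=inr, vii=vii)


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def make_paired_samples(
    patient: SyntheticPatient,
    t1: float = 3.0,
    t2: float = 4.0,
    params: PublishedParameters = PUBLISHED,
) -> SampleSet:
    """Two paired (INR, VII) samples at t1 < t2 days, deterministic per seed.

    Sampling before the factor VII equilibration threshold is permitted —
    the resulting set is flagged so negative-path tests can use it — but
    the prediction pipeline will reject such samples.
    """
    if t2 <= t1:
        raise DomainError(f"t2 must exceed t1 (got {t1}, {t2})")
    tc = simulate_time_course(patient, [t1, t2], params)
    samples = tuple(
        PairedSample(t=float(t), inr=float(i), vii=float(v))
        for t, i, v in zip(tc.times, tc.inr, tc.vii)
    )
    flags: tuple[str, ...] = ()
    if t1 < params.vii_equilibration_days:
        flags = ("pre_equilibration_sample",)
    return SampleSet(samples=samples, truth=patient, flags=flags)


def make_fixture_suite(
    out_dir: str | Path,
    params: PublishedParameters = PUBLISHED,
    seed: int = 0,
) -> dict:
    """Write a deterministic CSV fixture suite and return its manifest.

    Produces, for each dose in {1, 4, 7, 10, 13} mg/day: one noiseless
    dense time course (calibration round trips) and one noiseless
    day-3/day-4 paired-sample file (prediction round trips). Files are
    byte-identical across runs at the same seed; the manifest records the
    ground truths and SHA-256 digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # 0.05-day grid: keeps finite-difference truncation in the downstream
    # slope series well below the 0.1% calibration round-trip contract
    grid = np.round(np.arange(0.05, 30.0 + 1e-9, 0.05), 6)
    manifest: dict = {"seed": seed, "time_courses": [], "paired_samples": []}

    for dose in FIXTURE_DOSES:
        patient = SyntheticPatient(dref_true=dose, seed=seed)
        tc = simulate_time_course(patient, grid, params)
        tc_name = f"time_course_dose_{dose:g}.csv"
        lines = ["dose_mg_day,time_days,inr,factor_vii_pct"]
        lines += [
            f"{dose:g},{t:.6g},{i:.12g},{v:.12g}"
            for t, i, v in zip(tc.times, tc.inr, tc.vii)
        ]
        _write(out / tc_name, lines)
        manifest["time_courses"].append(
            {"file": tc_name, "dose_mg_day": dose, "sha256": _sha256(out / tc_name)}
        )

        ss = make_paired_samples(patient, 3.0, 4.0, params)
        ps_name = f"paired_samples_dref_{dose:g}.csv"
        pid = f"synthetic_dref_{dose:g}"
        lines = ["patient_id,time_days,inr,factor_vii_pct"]
        lines += [f"{pid},{s.t:.6g},{s.inr:.12g},{s.vii:.12g}" for s in ss.samples]
        _write(out / ps_name, lines)
        manifest["paired_samples"].append(
            {
                "file": ps_name,
                "patient_id": pid,
                "dref_true": dose,
                "dose_given": patient.dose,
                "inr0": patient.inr0,
                "sha256": _sha256(out / ps_name),
            }
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write(path: Path, lines: list[str]) -> None:
    path.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
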