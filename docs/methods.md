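# Methods

## Model and assumptions

The package treats factor VII as the principal driver of the non-steady-state
INR. The reasoning: of the vitamin K-dependent factors depressed by warfarin
(II, VII, X), factor VII turns over fastest (half-life ≈ 6 h), so it is the
first to reach its new steady state and dominates the early INR response;
once factor VII has settled, its level is also informative about where the
slower factors — and hence the steady-state INR — will end up.

The INR's sensitivity to factor VII, SI_VII = |∂INR/∂VII|, is approximated
as proportional to the observable ratio INR/VII (factor VII as % of the
pre-treatment baseline, so 100 at baseline):

    SI_VII(t) ≈ q · INR(t)/VII(t),   q = 0.233.

This approximation requires factor VII itself to be at steady state, which
is why samples in the first two days of therapy are rejected
(`vii_equilibration_days = 2.0`, configurable).

Steady-state INR is defined operationally: the INR is at steady state once
the SI_VII slope has decayed to a tolerance ε = 1.5·10⁻⁴ /day (`eps_si`).
The slope's time course is a three-parameter logistic whose asymptote h and
shift g depend on the reference dose D_ref (h = a0 + a1·D_ref affine,
g = b0 + b1·ln D_ref logarithmic, shape p = 0.300 /day fixed), and the rate
of INR change is a no-intercept quadratic in the slope with log-log
dose-dependent coefficients k < 0 and m > 0. These are empirical reductions
of a mechanistic coagulation-network model, valid for doses 1–13 mg/day and
INR 1.4–4.7; the package flags (but does not refuse) predictions outside
that envelope. g(D_ref) involves ln D_ref, so no reference dose exists for
a non-positive slope — such inputs are hard errors, as is D_ref ≤ 0.

## Closed forms and numerical choices

With u = p·(t − g), the two definite integrals needed for INR_SS have
closed forms built from ln(1+eᵘ):

* ∫ slope dt = (h/p)·[ln(1+e^(−u_lo)) − ln(1+e^(−u_hi))]
* ∫ slope² dt = (h²/p)·[F(u_hi) − F(u_lo)],  F(u) = 1/(1+eᵘ) − ln(1+e^(−u))

Both are written so that every term decays for u ≫ 0 (using the identity
u − ln(1+eᵘ) = −ln(1+e^(−u)) and the stable ln(1+eˣ) branch); the naive
forms lose all precision deep in the logistic tail, where the integrals are
dominated by tiny exponentials. Evaluation is finite and accurate for
arguments up to ±700. The test suite validates both against adaptive
quadrature to 1×10⁻⁸ relative on randomised instances.

t_SS,INR = g + (1/p)·ln(h/ε − 1), clamped at 0 when the tolerance is
already met at the start of therapy (including h ≤ ε).

D_ref inversion equates the observed finite-difference slope to the
*interval mean* of the logistic over [t₁, t₂], not the midpoint value: the
finite difference of the integrated model is exactly its interval mean, so
noiseless round trips are exact by construction. The midpoint variant is
available (`mode="midpoint"`). The root is found with Brent's method on the
fixed bracket (0.01, 50] mg/day (tolerance 1×10⁻¹⁰ absolute); strict
monotonicity of the interval-mean slope in dose over this bracket is
asserted in the test suite for the recommended sampling window. Dose-target
inversion (`dose_for_target_inr`) brackets on the supported reference-dose
range only.

Baseline INR defaults to 1.0 when unmeasured; INR_SS − INR₀ depends only on
D_ref, so a measured baseline simply shifts the prediction.

## Calibration

The fitters reproduce the model-order-reduction step from supplied data:

* `fit_q` — one-parameter regression through the origin (closed form);
  its r² uses the uncentered total sum of squares, the meaningful choice
  for a no-intercept model.
* `fit_logistic_family` — joint nonlinear least squares for (a0, a1, b0, b1)
  across all dose levels at once, p fixed at 0.300 by default or estimated.
* `fit_quadratic_family` — joint nonlinear least squares for (c0, c1, s0, s1).

Point estimation is unweighted least squares. Nonlinear fits start from
data-driven initial values (per-dose slope maxima and half-maximum crossing
times, per-dose linear solves for the quadratic) and run a deterministic
five-point multi-start schedule, keeping the lowest-cost converged
solution. Reported %RSE comes from the heteroscedasticity-robust sandwich
covariance (J'J)⁻¹ J'diag(r²)J (J'J)⁻¹ with n/(n−k) small-sample scaling:
measurement noise in these data is proportional to the signal, and the
plain (J'J)⁻¹·s² form understates the uncertainty of parameters dominated
by high-signal points. The original two-stage procedure (per-dose fits,
then dose-dependency regressions) survives only as the initial-guess
heuristic; the reported estimates are always from the joint fit.

`derive_slope_series` differentiates the SI series with second-order
central differences (second-order one-sided at the ends). Truncation error
scales with the square of the grid step; the packaged fixture generator
uses a 0.05-day grid, which keeps the refit error of every logistic
coefficient below 0.02%, well inside the 0.1% round-trip contract asserted
in the tests.

## Synthetic data: what it does and does not emulate

The generator exists so the whole pipeline can be exercised end to end with
known ground truth. It builds, for a chosen true reference dose:

* SI(t) = q·INR₀/100 + ∫₀ᵗ slope — the published logistic, integrated
  exactly;
* VII(t) — mono-exponential decline (half-life 0.25 days) to a plateau
  from a sigmoid dose-response 1 − I_max·Dⁿ/(Dⁿ + D₅₀ⁿ) with I_max = 0.9,
  D₅₀ = 5 mg/day, n = 2;
* INR(t) = SI(t)·VII(t)/q, so the SI identity holds exactly by
  construction.

The dose-response constants were chosen to satisfy two structural
constraints simultaneously over the calibrated 1–13 mg/day range: the
constructed INR must rise monotonically from baseline (at low dose this
requires the early relative VII decline, ln2·(1−f)/t½, not to exceed the
relative SI rise, slope(0)/SI(0) — suppression must be shallow at 1 mg/day)
and must stay within plausible INR magnitude at high dose (suppression must
be deep at 13 mg/day). A first-order saturating dose-response cannot meet
both; the Hill exponent of 2 opens a feasibility window (any D₅₀ roughly
in 3–8 mg/day works) and 5 mg/day sits in its middle.

Optional measurement noise is proportional log-normal with unit mean,
applied independently to INR and VII after the deterministic construction,
with an explicit seed.

What passing round trips do **not** show: the VII trajectory and the
resulting INR magnitudes are surrogates, milder than typical clinical
factor VII suppression; the generator's literal dINR/dt contains a
factor VII-kinetics term and is therefore *not* described by the quadratic
map, and the generator makes no attempt to reproduce mechanistic
simulations of the coagulation cascade. The algorithm consumes INR and VII
only through the ratio identity, so none of this affects the correctness
claims the round trips test — but agreement on synthetic data is not
evidence about real patients, for whom the proportional-SI and logistic
assumptions are empirical.

Consequences for calibration testing: quadratic-map recovery is checked on
series generated directly from the published sub-models (slope from the
logistic, dINR/dt from the quadratic), and the CLI's `calibrate` on raw
time courses — which differences the INR column — should not be expected
to reproduce the published quadratic coefficients on synthetic data.

## Problem sizes and statistical checks

Calibration checks use five dose levels (1, 4, 7, 10, 13 mg/day) on a
0.5-day grid to 30 days (60 points per dose); noisy-recovery coverage uses
100 seeded replicates at 5% proportional noise, requiring each coefficient
within 3 reported SE in ≥ 93% of replicates. The noisy paired-sample
recovery check uses 2000 replicates at 10% noise: roughly 16% of noisy
pairs yield a non-positive slope and have no reference dose; these are
treated as censored low (recorded as 0) so the median over all replicates
remains an unbiased location estimate, and 2000 replicates keep the
median's own Monte-Carlo error (~1.4%) small against the 5% accuracy band
being verified.

## Known limitations

* Constant dosing only: times are days since the most recent dose-rate
  change, and multi-rate histories are rejected rather than integrated
  piecewise.
* No uncertainty propagation from the published %RSE values into
  predictions, and no Bayesian updating.
* The equilibration guard is a fixed threshold; patients with abnormally
  slow factor VII turnover would need later samples, which the method
  cannot detect from a single pair.
* ε is a published operating point; the package does not re-derive it.
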