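# Methods

## Scope and model

`lvuq` implements a sensitivity-analysis (SA) and inverse-uncertainty-
quantification (I-UQ) workflow for the passive filling of the left
ventricle (LV) described by the Holzapfel–Ogden (H-O) orthotropic
hyperelastic strain-energy function

    Psi = a/(2b) [exp(b (I1 − 3)) − 1]
        + Σ_{i∈{f,s}} a_i/(2b_i) [exp(b_i (max(I4i,1) − 1)²) − 1]
        + a_fs/(2b_fs) [exp(b_fs I8fs²) − 1],

with invariants of C = FᵀF: I1 = tr C, I4f = m0·C m0, I4s = s0·C s0,
I8fs = m0·C s0 along the reference fibre (m0) and sheet (s0) directions.
The max() switch lets fibres and sheets resist extension only; its
derivative at exactly I4 = 1 is defined on the compression branch (zero),
so Psi is C¹ but not C² across the switch.  Cauchy stress for the
incompressible material is the push-forward of the energy derivative minus
a Lagrange-multiplier pressure; because the energy is only defined on the
isochoric manifold, the spherical part of the unconstrained derivative is
indeterminate and the implementation reports the deviatoric gauge
(`tau = dev(tau_bar) − p I`), which leaves every observable stress
difference unchanged.  An exponential-overflow guard raises a structured
`NumericRangeError` (identifying the offending term) rather than returning
infinities, since exponents up to b = 10 over wide strain ranges can
overflow double precision.

Stiffness-like constants (a, a_f, a_s, a_fs) are in kPa; exponents are
dimensionless; cavity pressures are in mmHg and converted with
1 mmHg = 0.133322 kPa only inside the inflation solver.

## The desk-scale forward model (synthetic-data generator)

The image-derived finite-element LV that a full-scale study would use is
replaced
by the semi-analytic inflation of an incompressible thick-walled cylinder
(default R_i = 25 mm, R_o = 35 mm, L = 80 mm; reference cavity volume
≈ 157 ml) with a rule-based fibre architecture: the helix angle varies
linearly through the wall from alpha_endo (default 60°) to alpha_epi
(default −90°), the sheet angle from +45° to −45°.  A cylinder rather
than a sphere was chosen because it admits helical fibres and
distinguishes circumferential, longitudinal and radial strains.

The deformation family r(R) = sqrt(r_i² + (R² − R_i²)/λ_z), z = λ_z Z is
exactly isochoric.  The two unknowns (r_i, λ_z) solve (i) radial
equilibrium, EDP = ∫ (τ_θθ − τ_rr)/r dr across the wall, and (ii) the
closed-tube reduced axial force balance ∫ (2τ_zz − τ_θθ − τ_rr) r dr = 0,
both p-free because only stress differences enter.  Integrals use
fixed-order Gauss–Legendre quadrature (default 16 points; a convergence
test covers the order).  Because the response is hyperelastic and the
loading quasi-static, only the final end-diastolic pressure (EDP) is
solved — path-equivalent to a linear pressure ramp.  A residual above
1e−8 kPa, or overflow, is a structured `SimulationFailure`; a pressure-
continuation fallback (10-step ramp re-using each solution as the next
initial guess) rescues most soft configurations.  Genuinely unstable
configurations (near-zero stiffness at high pressure, where inflation has
no bounded solution before the exponentials stiffen) fail and are dropped
with a log record, mirroring the mesh-distortion dropouts familiar from
finite-element LV models; across the log-uniform material box the failure
rate is a few percent.

Quantities of interest: cavity volume LVV = π r_i² λ_z L (ml) and 24
segmental Green–Lagrange strains (4 short-axis slices × 6 AHA-style
sectors), referenced to end-diastole via F̃ = F⁻¹, so all strains vanish
at zero load, circumferential strains are negative and radial strains
positive on inflation.  Segmental heterogeneity — absent from an ideal
cylinder — is emulated by deterministic, seeded per-segment wall-thickness
multipliers (mean 1, ±10%, moving the mid-wall sampling radius) and
per-slice axial factors (mean 1, ±5%), making the 24 strains of each type
distinguishable, which the 25-output emulator and the likelihood need.

What the generator does *not* emulate: image-derived geometry, the basal
boundary condition, apical torsion, residual stress, regional material
heterogeneity, and model discrepancy between simulator and reality.
Passing tests therefore demonstrate correctness of the statistical
machinery on a faithful desk-scale analogue, not fidelity to a specific
subject.

Input space (design bounds): the eight material constants on [0.1, 10]
(kPa or unitless), EDP on [4, 30] mmHg, alpha_endo on [0°, 90°],
alpha_epi on [−90°, 0°].  The reduced parameterization fixes a_s = 0.69
kPa, b_s = 1.11, a_fs = 0.31 kPa, b_fs = 2.58 (literature values) and the
angles at 60°/−90°.  Observation noise follows the two-component model:
volume + N(0, σ0²) with σ0 = 5 ml, each circumferential strain +
N(0, σ̃²) with σ̃ = 0.03; longitudinal and radial strains are not
observed.

## Gaussian-process emulation

One independent zero-mean GP per scalar output with the
automatic-relevance-determination squared-exponential kernel plus nugget.
The eight material inputs are log-transformed (the response varies much
faster for soft configurations; the log improves stationarity), then all
inputs are standardized per dimension; outputs are standardized to zero
mean and unit variance.  Hyperparameters maximize the log marginal
likelihood (L-BFGS-B with analytic gradients, 5 seeded restarts by
default, lengthscales bounded in [1e−2, 1e2] standardized units, nugget
floored at 1e−6).  For training sets beyond `max_opt_subset` (default
512) the likelihood is maximized on a seeded random subset and the model
then conditions on the full set — an O(n³)-saving choice that leaves
predictions using all data.  Joint posterior function draws over large
designs use decoupled pathwise (Matheron) sampling with a random-Fourier-
feature prior (default 1024 features) plus an exact update term; its
exchangeability with dense sampling is tested on small designs.
Predictive accuracy is scored with Q² = 1 − SSE/SST on held-out
simulations.

Known limitation (measured by the acceptance suite, not hidden): on the
full 11-input two-block design the cylinder's volume response is rougher
than that of a constrained finite-element ventricle — unconstrained ballooning under the
log-uniform prior spans roughly 170–1800 ml with quasi-exponential growth
in the soft corner — and the stationary zero-mean ARD-SE GP reaches
held-out Q² ≈ 0.90 for LVV (≈ 0.96–0.98 for the circumferential strain)
even with full-data hyperparameter optimization; an independent reference
GP implementation reproduces the same ceiling.  On the reduced
five-input space used for inference, both outputs reach Q² ≥ 0.99, so
the I-UQ study is unaffected.

## Sobol sensitivity analysis

Pick-freeze designs (A, B, A_B^(i)) are built from one scrambled Sobol
sequence mapped through the prior's inverse CDF; estimators are the
Saltelli-2010 first-order form mean(y_B (y_ABi − y_A))/V and the Jansen
total-effect form mean((y_A − y_ABi)²)/(2V) — the defaults of the
standard SA tooling.  Estimates are clipped to [−0.05, 1.05] with a
warning outside [0, 1]; ensembles over GP posterior draws (default 250)
quantify surrogate uncertainty and are summarized by mean, quartiles and
central 95% intervals.  The full study (SA1) varies all eleven inputs
under a uniform and a log-uniform material prior, for four outputs (LVV
and the pre-selected inferior-lateral segment strains of the second
slice); the fixed-pressure study (SA2) sweeps EDP over {5, 7.5, …, 25}
mmHg with the reduced parameterization.  Base sample default N = 4096; scaled runs in the test suite use
N = 1024/512, where the qualitative orderings are already stable.

## Bayesian inverse UQ

The likelihood is the two-component Gaussian of the noise model, with the
25 forward predictions replaced by GP posterior means (emulator variance
is deliberately not propagated — a known bias source).  Priors are
uniform on the natural parameter scale over [0.1, 10] for (a, b, a_f,
b_f) and uniform on σ̃ over [1e−4, 0.2] (the strain-noise scale is
inferred; the volume-noise variance is fixed, being non-identifiable from
a single measurement).  Sampling runs in an unconstrained space via a
logit-of-log map whose Jacobian reproduces those priors exactly, using an
in-package multinomial No-U-Turn sampler (dual-averaging step size
targeting 0.8 acceptance, diagonal mass estimated mid-warmup, tree depth
capped at 8).  Five chains start from a scrambled Sobol sequence over the
prior box; defaults are 1000 warmup + 2000 draws per chain.  Convergence
uses the classic Gelman–Rubin PSRF, √(((n−1)/n · W + B/n)/W), with the
threshold 1.01; identifiability is summarized by the inverse
interquartile range (I-IQR) of each natural-scale marginal, and battery
tables attach LVV-quartile bins cut at the 0.25/0.5/0.75 quantiles of the
battery's own noise-free volumes at EDP = 10 mmHg.

## Stress–stretch push-forward

Each posterior draw defines a homogeneous uni-axial stretch test along
the fibre or sheet direction: the two lateral stretches solve
incompressibility plus zero lateral stress (full two-variable root find,
seeded by the equal-lateral isotropic solution, since orthotropy makes
the lateral directions inequivalent).  Default stretch grid {1.02, 1.05,
1.10, 1.15, 1.20, 1.25, 1.30}; default thinning 500 draws per case.
Spread is summarized by the stress I-IQR per stretch level and accuracy
by the median inverse absolute error against the known true curve, with
infinite values capped at 1e6 and flagged.

## Problem sizes used by the test suite

The default test run uses scaled study sizes chosen as the package's
standard desk-scale battery: 2000 + 100 simulations for the full-design
emulators and 2000 + 48 for the reduced-space bank (the study's training
size; anything smaller leaves volume-emulator bias comparable to the 5 ml
measurement noise); a 21-case posterior battery at 10 mmHg plus 8
half-noise cases (2 chains × 200 warmup + 300 draws each) and 5 cases × 5
pressures for the identifiability trends (2 chains × 150 + 200); the
convergence check runs 5 chains × 600 + 1200 on the reference case; SA
ensembles use 30–50 GP draws at base sample N = 512–1024.
The posterior-gradient hot path is evaluated by a compiled (numba) fused
kernel that is asserted equivalent to the plain numpy reference
implementation.  `scripts/acceptance.py` recomputes the convergence
quantity at the full sizes (2000-point design, 5 chains × 1000 + 2000).

A second measured limitation: posterior contraction under halved
observation noise is not monotone marginal-by-marginal on this surrogate.
The reduced-parameter posteriors are ridge-shaped (a trades off against
a_f, b against b_f); halving both noise SDs sharpens the ridge
transversely and moves it with the re-drawn observation, but the marginal
interquartile range along the ridge can stay flat or grow for a given
realization, and battery medians over feasible case counts tie to within
Monte-Carlo noise for the exponents.  The acceptance suite states the
contraction check as a strict per-parameter median decrease and reports
it as failing; interval coverage for the stiffness parameter passes.

## Numerical choices and tie-breaks

- Derivative of the anisotropic terms at exactly I4 = 1: zero
  (compression branch).
- Inflation solver tolerance 1e−8 kPa on both residuals; quadrature
  order 16; initial guess (1.05 R_i, 1.01) with a 10-step pressure ramp
  fallback.
- GP jitter escalation on Cholesky failure; eigen-clipped factor for
  sampling covariances that are PSD only to rounding.
- Sobol-index clipping [−0.05, 1.05] for display; raw draws retained in
  ensembles.
- NUTS divergence threshold: Hamiltonian error 1000; divergences counted
  post-warmup only.
- I-IQR and stress I-IQR raise structured errors on zero IQR (degenerate
  posteriors) instead of returning infinity.
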