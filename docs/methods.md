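# Methods

This note documents the statistical model behind `aggpk`, the numerical
choices made where the design was genuinely open, and what the synthetic
test conditions do and do not demonstrate.

## Model and likelihoods

Observations follow the standard nonlinear mixed-effects form
y_ik = f(θ_i, ξ_ik) + h(θ_i, ξ_ik, ε_ik) with θ_i = g(β, b_i),
b_i ~ N(0, Ω) and independent normal residuals whose variance is
σ₁² (additive), f²·σ₂² (proportional) or their sum (combined). The
individual-parameter map defaults to lognormal, θ = β⊙exp(b), the usual
choice for PK parameters that must stay positive; an identity map is
available for models linear in their random effects.

Aggregate data are the observed per-timepoint mean vector ȳ and the K×K
observed covariance matrix V with the **population (1/N) denominator**. The
denominator is not negotiable plumbing: with 1/N, the aggregate-data FO
log-likelihood

    log L(ȳ, V | Ψ) = −(N/2)[ tr(V Ṽ⁻¹) + (ȳ−ỹ)ᵀ Ṽ⁻¹ (ȳ−ỹ) + log|Ṽ| ]

is algebraically identical to the sum of per-subject FO log-likelihoods, a
property the test suite asserts to 1e−8 on simulated cohorts and which also
makes (ȳ, V, N) a sufficient statistic under FO. With 1/(N−1) the identity
fails. For N = 1 the covariance is exactly zero and the expression collapses
to the individual-data log-likelihood.

No 2π constants are carried anywhere, so OFV = −2·log L matches the
extended-least-squares objective printed by standard pharmacometric
software. This differs from a textbook MVN log-density by K·log 2π per
subject and is deliberate; all objective values reported by this package are
on that scale.

### Expected-moment approximations

- **FO**: linearization at b = 0. The Jacobian ∂f/∂b is obtained by central
  differences with step 1e−5·max(1, |b_j|); analytic Jacobians can be
  registered per model but the finite-difference path is the reference.
- **FOCE(I)**: the FO-form mean and covariance expressions evaluated at each
  of N_sim quasi-random b vectors and averaged, with the mean re-centered by
  the Jacobian correction f(θ_i) − J_i·b_i. The interaction variant (FOCEI)
  evaluates the residual-variance magnitude at each sampled individual
  prediction; plain FOCE evaluates it at the typical-value prediction. Both
  are exposed because the two conventions give different objective values
  for proportional error.
- **MC**: empirical mean and covariance (1/N_sim denominator in both the
  spread term and the averaged residual diagonal) of residual-free simulated
  predictions. For symmetric residual distributions this converges to the
  exact moments, so the MC aggregate method inherits consistency when the
  analytic and generating models coincide.

The residual contribution to every predicted covariance is a diagonal
matrix: residuals are independent across observations, and Σ itself is
diagonal (no additive–proportional correlation). Predicted covariances are
re-symmetrized after assembly; with σ_add² > 0 their spectrum is bounded
below by σ_add², which keeps Cholesky factorizations stable.

### Quasi-Monte-Carlo integration

Integration over random effects uses unscrambled Sobol points mapped through
the inverse standard-normal CDF and a Cholesky factor of Ω. The all-zero
first Sobol point is dropped (the inverse CDF is undefined there). Points
are deterministic for fixed (v, N_sim); the default N_sim is
max(300, N subjects). The adequacy of 300 is not assumed but measured: the
leave-one-out diagnostic (`loo_mc_se`) recomputes the aggregate
log-likelihood N_sim times with one vector excluded and reports the standard
deviation per subject in the dataset. At the two-compartment study
conditions this lands at a few ×1e−4 log-likelihood units per subject —
negligible against parameter-scale likelihood differences. Pseudo-random
residual noise (seeded `numpy` Generator) is used only for simulating
datasets, mirroring the split between integration and simulation.

## Estimation

Positive quantities (fixed effects under the lognormal map, all variances)
are optimized on the log scale. Ω off-diagonals are fixed (zero by default)
and not estimated; none of the built-in study conditions define
random-effect correlations. For the QMC methods the standard-normal Sobol
points are drawn once per fit and held fixed across outer iterations
(common random numbers); each candidate Ω only re-correlates them, so the
objective is deterministic and smooth enough for quasi-Newton steps.

The optimizer alternates a bounded adaptive Nelder–Mead stage (coarse
tolerances) with an L-BFGS-B polish, restarting the simplex at the incumbent
until an alternation no longer improves the objective (at most a handful of
rounds). Restarting with a re-inflated simplex is what rescues Nelder–Mead
from the premature stalls it is prone to in ten-plus dimensions; the polish
supplies the final precision (relative function tolerance 1e−10).

The search is confined by default to ±3 log units (a factor ~20) around the
initial estimates. Approximate NLME likelihood surfaces — especially with a
misspecified structural model — can contain degenerate modes in which a
fixed effect runs to zero while its variance inflates essentially without
bound (observed here: CL → 0 with ω²_CL > 10³ under a transit-generating /
first-order-analytic mismatch, with a marginally better objective than the
principal mode). The box keeps every fit, whether a single analysis or an
SSE replicate, on the principal mode so that replicate summaries describe
one estimator rather than a mixture; pass `log_bound_width=None` for an
unconstrained search. Evaluations with a non-positive-definite predicted
covariance return −1e10 minus the magnitude of the most negative eigenvalue,
a finite repulsive penalty that derivative-free stages tolerate.

Standard errors are observed-information: a central-difference Hessian of
the negative log-likelihood on the **natural** parameter scale (relative
step 1e−4), inverted; RSE% = 100·SE/|estimate|. A non-invertible Hessian or
non-positive variance leaves SEs absent with an explanatory flag rather than
a number.

Inner MAP estimation for FOCE(I) on individual data minimizes the
conditional negative log-posterior by BFGS from b = 0 (gradient tolerance
1e−8), warm-starting each subject from the previous outer iteration's
estimate. The residual variance inside the MAP objective is evaluated at the
candidate prediction.

## Optimal design and the SSE replacement

The expected FIM is the negative numerical Hessian of the aggregate-data
log-likelihood, evaluated at expected aggregate data simulated from the
generating model. Because the expected data can come from a *different*
model than the one whose parameters are differentiated, this covers
misspecified-design questions that classical FIM expressions cannot. The
Hessian uses central differences with one Richardson refinement at relative
step 1e−3 on the natural scale. That step is deliberately larger than the
SE Hessian's: the nested finite-difference Jacobian inside the FO moments
leaves ~1e−10-relative noise on the log-likelihood, and at step 1e−4 that
noise is amplified enough to distort FIM entries lying several orders of
magnitude below the dominant ones; at 1e−3 (with Richardson) the Hessian
route and the independent linearized-FIM route agree entrywise to ~2e−5.
The independent cross-check, `fo_fim_linearized_oracle`, implements the
standard MVN information identity I_jk = N[dỹᵀṼ⁻¹dỹ + ½tr(Ṽ⁻¹dṼṼ⁻¹dṼ)] from
moment gradients (central differences, relative step 1e−4) and shares no
code with the Hessian path beyond the FO moments themselves.

`aggregate_od` is the one-step replacement for stochastic simulation and
estimation: simulate expected aggregate data once from the generating model
(MC approximation by default, since that is the asymptotic truth of the
generator), fit the analytic model to it, attach Hessian-based expected SEs.
`run_sse` provides the classical replicated alternative; replicate seeds are
master-seed + counter, so individual-mode and aggregate-mode runs with the
same seed fit the same underlying datasets, and per-replicate failures are
recorded rather than fatal, with converged counts reported alongside
summaries.

## Built-in study conditions

- **Monoexponential decay** (`wang`): f = 10·exp(−k·t), one lognormal random
  effect on k; evaluation point k = 0.5, ω² = 0.04, σ² = 0.1 with additive
  or proportional error. The published 10-subject dataset for this model is
  user-supplied (`data/wang2007.csv`); it is deliberately not bundled.
- **Two-compartment oral** (`twocomp_oral`): CL 5 L/h, Vc 10 L, Vp 30 L,
  Q 10 L/h, ka 1 h⁻¹; lognormal IIV with log-SD 0.3 on all five parameters;
  additive residual SD 0.2 mg/L; 100 mg single dose at t = 0; sampling at
  0.1, 0.25, 0.5, 1, 2, 3, 5, 8, 12 h. Evaluated in closed tri-exponential
  form (eigenvalues of the disposition system; coincident rate constants
  resolved by a 1e−10-relative perturbation of ka), verified against an
  adaptive ODE solve to ~1e−13 relative error.
- **Transit-compartment generator** (`transit2`): mean transit time 1 h with
  two transit compartments. The transit-rate convention here is
  ktr = (n+1)/MTT = 3/MTT with the depot counted as the first of the three
  chain steps, i.e. an Erlang(3, ktr) input into the central compartment —
  one of two conventions in circulation, chosen so that MTT equals the mean
  time to reach the central compartment. The generator keeps the
  two-compartment disposition (CL, Vc, Vp, Q as above), puts log-SD 0.3
  lognormal IIV on MTT and the disposition parameters, and uses the same
  100 mg dose and additive SD 0.2 mg/L; dose and residual level are design
  choices where the study conditions leave them open. Evaluated by closed-form
  Erlang-input convolution, verified against the ODE representation.

## What the synthetic conditions show — and what they do not

The simulated cohorts are balanced (every subject on the same grid), have no
dropout, no below-quantification censoring, no covariates and no
inter-occasion variability, and their residuals are exactly normal —
simulated concentrations may therefore be slightly negative and are retained
as such, consistent with the likelihood. Passing tests demonstrate the
internal consistency and asymptotics of the estimators under these idealized
conditions: the FO aggregate/individual identity, convergence of MC moments
and estimates to truth, FIM equivalence, and agreement of the one-step OD
procedure with replicated SSE. They do not demonstrate robustness to
unbalanced designs, censoring, non-normal random effects, or covariate
structure, none of which the aggregate expressions currently cover. Because
aggregate data carry only the first two moments, aggregate-data estimation
assumes normality of the data distribution outright and is expected to be
less robust to structural misspecification than individual-data methods —
visible here in the transit-generator study, where individual-data and
aggregate-data fits of the misspecified model land on different estimates.

## Problem sizes used in the shipped checks

Test problem sizes were chosen as the smallest that make each property
sharp: cohorts of 10–250 subjects for identity checks, 3000 subjects /
N_sim 3000 for MC parameter recovery (fixed effects recovered within 10%),
1000 subjects / N_sim 300 for the leave-one-out diagnostic, N = 100 for FIM
comparisons, and 50 replicates of N = 100 for the SSE-versus-OD study. The
acceptance script reruns the leave-one-out diagnostic at those same
conditions from a fresh simulation each time.
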