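# Methods

## The model

Each longitudinal variable V (outcome Y, continuous treatment A,
confounders L), measured on a fixed grid of waves t_0..t_K, is assumed to
decompose additively into a temporal group mean, a time-invariant
*stable-trait* factor I, and a time-varying *within-person variability
score* V*:

    V_ik = mu_k + I_i + V*_ik,   Cov(I_i, V*_ik) = 0.

The trait is a random intercept with unit loadings at every wave: it
shifts a person's whole trajectory but does not enter the lagged dynamics
(it is *not* a time-invariant confounder of the within-person process).
The causal estimand is the joint effect, at the within-person level, of a
sequence of treatment-score increments on a later outcome score,
E(Y*_k under setting the history of A* ) = sum_t beta_{k t} a*_t, under
consistency, sequential ignorability given the within-person history,
positivity, SUTVA, modularity, and (for the first step) multivariate
normality.

Estimation is a deliberate two-step:

1. **Step 1 (per variable).**  Sigma = phi^2 11' + Psi(theta) is fitted by
   maximum likelihood with a structured within-person covariance Psi.
   Stable-trait scores are predicted by the linear correlation-preserving
   predictor, cross-variable trait covariances are taken from those
   predictions, the stacked within covariance is Psi_hat = S − Phi_hat^+
   (trait covariances expanded over all-ones time blocks), and
   within-person scores are predicted by the weight matrix
   W' = Psi^{1/2}(Psi^{3/2} Sigma^{-1} Psi^{3/2})^{-1/2} Psi^{3/2} Sigma^{-1},
   the minimum-trace-MSE linear predictor subject to W' Sigma W = Psi.
2. **Step 2 (on the predicted scores).**  Either a marginal structural
   model fitted by weighted least squares with stabilized inverse-
   probability weights built from normal linear treatment models, or a
   linear structural nested mean model solved by G-estimation of
   conditional-covariance moment conditions, which is doubly robust in its
   two nuisance models (treatment assignment, and the conditional mean of
   the blipped-down outcome).

Separating the steps keeps misspecification of the within-person
structural dynamics out of the measurement model, allows non-linear
treatment-assignment models, and sharply reduces the incidence of improper
solutions relative to simultaneous SEM estimation.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `psi_structure` | structure of Psi(theta) | `ar1_timevarying` | first-order autoregression with per-transition coefficients and per-wave innovation variances; the least restrictive identified choice on short panels, and the structure used throughout the study |
| `estimator` | discrepancy in step 1 | `ml` | GLS available as an option |
| `missing` | missing-data handling | `fiml` | full-information likelihood over each person's observed coordinates; valid under MAR |
| `phi2` (generator) | stable-trait variance | 10 | together with within-score variance ~10 this puts the trait share near 50%; the study grid also uses 10/9 (10%) and 30/7 (30%) |
| `residual_variance` (generator) | within-process innovation variance | 5 | about half of the within-score variance is explained by the lagged state |
| `trait_correlation` (generator) | correlation of the three traits | 0.3 | moderate between-person confounding |
| blip `interactions` | treatment-by-confounder moderation terms | off for the simulation study, on for cohort-shaped analyses | matches the two uses of the SNMM |
| bootstrap `B` | person-level bootstrap resamples | 500 | second-step standard errors; the resampling unit is the person |

All variances are on the measurement scale (squared units of the
variable); time is a 0-based wave index on the fixed grid.

## The synthetic-data generator

The generator is the study's data-generating process: initial within
scores (Y*_0, A*_0, L*_0) drawn with variances 10 and covariances 3;
thereafter Y* and L* evolve by fixed first-order linear equations
(0.40, 0.40, 0.10 and 0.20, 0.20, 0.50) and the treatment score responds
to the *concurrent* outcome and confounder scores
(A*_k = 0.20 Y*_k + 0.40 A*_{k-1} + 0.30 L*_k + d); all residuals are
independent normals with variance 5.  Traits are an independent
multivariate normal.  Measurements are trait + within score, with the
treatment recorded at waves 0..K−1 (0..K when K = 2, where three waves
are needed to identify the measurement model).  Three misspecification
scenarios perturb this: additive measurement error (10% or 20% of the
initial measurement variance), trait loadings that grow over waves and
cross variables (the trait stops being a stable trait), and a quadratic
concurrent-outcome term (coefficient 0.08) in the treatment assignment.

Two calibration facts deserve note, because they are easy to get wrong:

- **The process is not exactly stationary.**  Started from the (10, 3)
  covariance with independent variance-5 residuals, the wave covariance
  drifts upward (within-score variances ~10.7 at wave 2, ~12.1 at wave 4;
  the limiting solution of the discrete Lyapunov equation has diagonal
  ~14.2).  Exact stationarity at (10, 3) would require innovation
  covariance S0 − A S0 A' — whose diagonal is ≈ (5.26, 5.45, 5.26) but
  which has negative off-diagonals — i.e. *correlated* concurrent
  residuals, which would in turn make every first-order treatment model
  misspecified and bias even the true-score estimators.  The generator
  therefore keeps independent residuals; `implied_wave_covariances`
  exposes the exact finite-wave covariances (what simulated moments are
  tested against) and `implied_stationary_covariance` the Lyapunov
  limit.  None of this affects the causal coefficients, which depend only
  on the path coefficients.
- **What passing tests do and do not show.**  The generator has
  homogeneous linear dynamics, normal residuals, complete data by default
  (an MAR dropout switch exists), and a single confounder; recovery
  results under it do not speak to heterogeneous effects, non-normal
  measurement, or MNAR missingness in real panels.

## The analytic effects oracle

For any linear first-order process the coefficient of an intervened
a*_t on E(Y*_k) is computed by severing the treatment equation
(modularity) and propagating the unit impulse through the (Y*, L*)
subsystem: seed (beta_Y, beta_L) at wave t+1, multiply by the transition
matrix [[alpha_Y, gamma_Y], [alpha_L, gamma_L]] per subsequent wave, and
read off the Y component.  The study's coefficients give the triangle
(0.40; 0.18, 0.40; 0.09, 0.18, 0.40; 0.0486, 0.09, 0.18, 0.40), and an
eight-wave design intervening only the last four treatments reproduces the
same ten values.  All Monte-Carlo bias/RMSE tables are scored against this
oracle; a simulation-based interventional check (forcing a vs a+1)
verifies it independently in the tests.

## Numerical choices

- **Step-1 optimization.**  Variances are optimized on the log scale
  (positivity without constraints) with L-BFGS-B from three deterministic
  starts (moment-based, shrunk, diffuse); with complete data the likelihood
  is evaluated from sufficient statistics (sample mean profiled out), with
  missing data by missingness-pattern FIML.  Estimates at the variance
  boundary (below 1e-3 of the variable's variance scale) are flagged
  *improper* — the analogue of negative-variance solutions in unconstrained
  covariance-structure software — and the study runner discards and counts
  those replications; they are never silently repaired.
- **Fit indices.**  CFI (baseline: independence model with free means and
  variances), RMSEA, and SRMR from the standard likelihood-ratio
  statistics; computed for complete-data fits.
- **Matrix powers.**  All fractional powers in the weight matrix go
  through symmetric eigendecompositions with eigenvalues clipped at 1e-8;
  Psi_hat = S − Phi_hat^+ is eigenvalue-repaired to PSD when sampling
  error makes it slightly indefinite (the repair is reported).  Persons
  with missing cells get pattern-specific weights from S and Psi_hat
  restricted to their observed coordinates.
- **Stabilized weights.**  The density-ratio product runs over the
  intervened treatment occasions *including the first one*, whose
  numerator is the marginal treatment density and whose denominator
  conditions on the concurrent outcome/confounder scores.  The first
  treatment score is correlated with the initial state, so omitting its
  factor (a product starting at the second occasion) leaves that
  confounding uncontrolled and biases the earliest-treatment coefficient
  from 0.40 toward 0.55 under the study process; the strict
  second-occasion-onwards product remains available via
  `include_first_occasion=False`.  Weights are not truncated by default;
  percentile truncation is an option.
- **G-estimation.**  One moment condition per blip parameter: the
  model-A-residualized treatment (times the concurrent confounder for
  moderation terms) against the model-B-residualized blipped-down outcome.
  With the identity link the system is affine in tau, so the Newton step
  is exact: the solver assembles and solves the linear system directly,
  rejects it when the condition number exceeds 1e12, and verifies the
  scaled residual norm (< 1e-8) of the moment conditions at the solution.
  Reciprocal residual variances V are computed for reporting; in the
  just-identified system they do not move the solution.
- **Eight-wave designs.**  Only waves 4..7 are intervened; earlier
  treatments enter the MSM as covariates and the SNMM histories as
  conditioning variables, so the ten causal parameters coincide with the
  four-wave design's.
- **Rank deficiency.**  Person-mean centering forces each person's
  centered treatment scores to sum to zero, so the final-horizon design is
  exactly collinear; the fit flags the horizon and reports its
  coefficients as unavailable rather than dropping columns silently.

## Design choices where the design was open

- The off-diagonal trait covariances come from the correlation-preserving
  trait predictions.  These attenuate by the squared trait-prediction
  reliability (a correlation of 0.3 is recovered as ≈ 0.21 at five waves)
  even under a correctly specified model, and prediction-level trait and
  within-score estimates are *not* orthogonal (≈ 0.6 correlation) although
  the latent quantities are; both facts are asserted in the tests rather
  than idealized away.  This is one source of the proposed method's small
  residual bias.
- Second-step standard errors use the nonparametric person-level
  bootstrap (B = 500 by default), the assumption-lightest choice for a
  two-step estimator whose first-step uncertainty would otherwise be
  ignored by analytic sandwich formulas for the second step alone.
- Mean and covariance inputs to the score predictor are the sample moments
  (pairwise-complete under missingness), not the model-implied ones; the
  model-implied covariance is available per variable.
- The Monte-Carlo study defaults to 50 replications per cell (the full
  protocol is 200).  The true-score arm of the recovery check runs at the
  full 200 replications: it needs no measurement fits, and at 50
  replications the Monte-Carlo error of a bias estimate (~0.011 for the
  late-horizon IPW coefficients) is of the same order as the 0.02 bound
  being checked.

## Known limitations

- Only identity-link (linear) SNMMs; no logistic/log-link blips, no
  optimal-regime estimation.
- One treatment variable; confounders enter linearly in the default
  nuisance models (a quadratic outcome term is built in as the one
  non-linear extension the study needs).
- FIML assumes MAR; no MNAR sensitivity analysis.
- The measurement model carries no measurement-error (unique + error)
  decomposition; under the measurement-error scenario all methods absorb
  the error into the within scores.
- Fit indices are exact for complete data only; under missingness SRMR is
  computed from pairwise-complete moments and CFI/RMSEA are omitted.
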