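# Methods

This note records the models, priors, algorithms, and numerical choices
behind `microdyn`, including the places where a design was genuinely open
and what was decided.

## Dynamics models

**VAR.** The lag-1 vector autoregression is
`X_t = A X_{t−1} + c + ε_t`, `ε_t ~ N(0, diag(σ²))`, on an integer (unit
lag) time grid. The canonical synthetic study used throughout the tests and
the acceptance script drives this model with noise of standard deviation
1.5. VAR states are statistical quantities, not mechanistic abundances, so
simulated values may go negative; a `clip_negative` option exists but is
off by default.

**MVAR.** The species/metabolite coupling is simulated exactly in its level
form: `X_t = A ΔX_{t−1} + c_x + ε_x` and `S_t = B ΔX_{t−1} + c_s + ε_y`,
with `ΔX_{t−1} = X_{t−1} − X_{t−2}`. Because the right-hand side uses a
lagged difference, the level form is a lag-2 linear system whose companion
matrix is `[[A, −A], [I, 0]]`; `ρ(A) < 1` does **not** bound it (real
negative eigenvalues of A destabilize it), so the fixture generator
additionally rejection-samples on the companion spectral radius when a
stable fixture is requested. A documented `response="difference"` variant
puts `ΔX_t` on the left instead; the level form is the default and is never
silently "corrected". Two initial abundance rows are required (the
difference needs one step of history); metabolite rows 0 and 1 both take
the supplied initial value.

**gLV.** `dx_i/dt = x_i (μ_i + Σ_j M_ij x_j)` — the standard generalized
Lotka–Volterra form, with `M_ij` the per-capita effect of species j on
species i (units 1/(abundance·time)) and `μ` intrinsic growth rates
(1/time).

**CR.** MacArthur consumer–resource dynamics with linear uptake:
`dx_i/dt = x_i (Σ_k yield_ik·uptake_ik·R_k − death_i)` and
`dR_k/dt = supply_k − dilution·R_k − Σ_i uptake_ik·x_i·R_k`. This is the
simplest standard CR form; the parameter container is explicit so users can
swap in saturating uptake by subclassing the simulator.

ODE integration uses adaptive Runge–Kutta (`scipy.integrate.solve_ivp`,
RK45) at rtol 1e-8 / atol 1e-10 — tight enough that comparisons against a
brute-force fine-step Euler oracle isolate model error rather than solver
error. States are floored at zero against integrator overshoot. Measurement
noise for the ODE models is multiplicative log-normal applied per
observation, leaving the latent trajectory deterministic.

**Fixture generator.** `generate_fixture` draws A entries ~ Normal(0, 0.3)
and rescales to spectral radius 0.8 (stable) or 1.25 (unstable); intercepts
are zero for VAR. gLV fixtures use negative self-limitation diagonals and
weak random off-diagonals; CR fixtures use uniform positive rates. All
draws come from one seeded generator, so a seed fully determines parameters
and trajectory.

## Imputation

One independent GP per variable over time, fitted by maximizing the log
marginal likelihood with 5 random restarts (seeded), via scikit-learn's
`GaussianProcessRegressor` with `signal × RBF + white noise` (Matérn-3/2
available). The initial lengthscale is a quarter of the observed time span,
with bounds wide enough to reach near-interpolation or near-constant fits.
Predictions are reported with equal-tailed Gaussian bands that include the
fitted observation noise, so the bands are predictive intervals for new
observations (this is what band-coverage checks measure). The default band
level is 0.95 and is always an explicit argument. Targets are internally
standardized (`normalize_y`), so the GP prior mean is the training mean and
the prior variance is scaled back to the data scale; reversion far from
data is toward the training mean.

Variables are treated independently — no multi-output GP — which matches
per-taxon imputation practice but ignores cross-taxon correlation; imputed
values at a gap use only that taxon's history. An optional `log1p`
transform supports strictly nonnegative abundances (off by default).
`impute` replaces only masked entries; observed entries are bit-identical
before and after, and the provenance of filled cells is recorded in the
series metadata.

## Inference

All three inferable models reduce to multi-response linear regressions:
VAR regresses `X_t` on `X_{t−1}`; MVAR regresses `X_t` and `S_t` on
`ΔX_{t−1}`; gLV uses gradient matching — central-difference
`d(ln x_i)/dt` regressed on `(1, x)` — chosen over a full ODE posterior
for speed and testability at the cost of finite-difference bias on coarse
grids (a documented limitation). Missing entries are never dropped
silently: inference raises and points at the imputation module. A
relative-abundance flag converts rows to proportions first and stamps the
output with a non-identifiability caveat (compositional data cannot pin
absolute interaction scales).

**Linear route.** Per-equation OLS via QR (`scipy.linalg.lstsq`), classical
t-intervals, rank-deficiency detection that advises ridge; ridge penalizes
coefficients but never intercepts. The Gaussian log-likelihood at the MLE
feeds AIC (`2k − 2lnL`) and BIC (`k ln n − 2lnL`), with `n` the number of
scalar observations.

**Bayesian route.** Default priors: coefficients Normal(0, 1), intercepts
Normal(0, 5), noise scales half-Normal(1) — all overridable through
`PriorSpec`. The horseshoe option is a non-centered parameterization with
half-Cauchy local scales and a half-Cauchy global scale (default 1),
lightly regularized by a fixed slab of scale 2 for sampler stability — a
deliberate simplification of the full inverse-gamma slab hierarchy. The
LKJ prior (default η = 2, a mild preference for moderate correlations)
applies to residual correlation matrices and is parameterized through
canonical partial correlations: unconstrained values are tanh-mapped to
(−1, 1), the C-vine construction builds the correlation Cholesky factor,
and the matching scaled-Beta CPC densities make the implied matrix
LKJ(η)-distributed. LKJ is on by default for MVAR (both equations) and off
for VAR/gLV (independent noise).

Sampling uses emcee's affine-invariant ensemble with the **stretch move**.
This choice is load-bearing: the differential-evolution moves in the
installed emcee version measurably under-disperse (standard-normal target
sampled at sd 0.91; VAR posterior widths 0.84× an exact conjugate-Gibbs
oracle), while the stretch move reproduces both exactly. Walkers start
overdispersed at about twice the OLS standard error around the
least-squares solution — a tight initialization ball leaves the whole
ensemble under-dispersed in a way split-R-hat cannot detect. Defaults:
walker count `max(chains, 2·ndim + 2, 32)` (the `chains` setting is a
floor), 3000 burn-in steps, 2000 kept draws per walker at thinning 2.
Each walker is treated as a chain for ArviZ split-R-hat and bulk-ESS;
a mean acceptance fraction below 0.1 is recorded as a warning in the
diagnostics rather than failing silently. Models without an LKJ block use
a fully vectorized log-posterior over walkers; LKJ blocks fall back to a
per-walker Cholesky loop (cheap at the matrix sizes involved).

Posterior summaries are element-wise medians with equal-tailed quantile
intervals. The log-likelihood reported for information criteria is the
independent-Gaussian likelihood at the posterior medians.

## Stability

`stability_eigen` computes the full complex spectrum and classifies a
matrix stable iff the spectral radius is **strictly** below the threshold
(default 1): a modulus of exactly 1 is unstable. `posterior_stability`
pools all chains, classifies every draw, and separately classifies the
element-wise posterior-median matrix. The per-draw fraction and the
median-matrix verdict are deliberately independent quantities — a stable
median with a stable fraction below 100% is a meaningful statement about
posterior uncertainty, not an inconsistency.

## Synthetic data and what the tests show

The fixture generator emulates densely, regularly sampled panels with
Gaussian (VAR/MVAR) or log-normal (gLV/CR) noise, no compositional
constraint unless requested, no sampling irregularity, and no model
misspecification: the generating family is always the fitted family.
Passing tests therefore demonstrate correctness of the machinery —
simulators match hand-iterated recursions and an independent Euler oracle;
OLS matches a normal-equations oracle to 1e-8; credible intervals are
calibrated against ground truth (20 replicates of the 200-step, sd-0.5
study give 90% intervals covering at the nominal rate); GP bands cover
held-out draws from a known GP — not robustness to the misspecification,
irregular sampling, or compositional effects of real microbiome data.
Problem sizes in the test suite (200–300 timepoints, 2–3 taxa, 20
calibration replicates) were chosen as the smallest instances at which
these statistical checks are stable.

## Known limitations

- Lag-1 only; no higher-order VAR, no stochastic differential equations,
  no spatial structure.
- gLV inference is gradient matching, not an ODE posterior; accuracy
  degrades with coarse sampling. CR parameters are simulation-only.
- The horseshoe posterior mixes slowly under an ensemble sampler; R-hat
  for horseshoe runs should be inspected (the shrinkage *ordering* is
  robust, tail quantiles less so).
- Relative-abundance mode removes absolute-scale identifiability; results
  are interpretable only up to the compositional transform.
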