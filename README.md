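# microdyn

Simulation and Bayesian inference of microbial community dynamics from
longitudinal data.

Microbiome time series — taxon abundances, optionally paired with metabolite
concentrations — carry information about who interacts with whom: which
species promote or suppress each other, and which abundance shifts drive
metabolite production or consumption. `microdyn` turns such tables into
interaction networks with quantified uncertainty, and provides the
simulators needed to test any such claim against data of known ground truth.

## What it does

**Simulate** communities under four generative families:

- **VAR** — lag-1 vector autoregression, `X_t = A·X_{t−1} + c + ε_t`, with
  Gaussian noise; the workhorse statistical model for densely sampled
  series.
- **MVAR** — a two-equation species/metabolite coupling:
  `X_t = A·ΔX_{t−1} + ε_x` and `S_t = B·ΔX_{t−1} + ε_y`, where
  `ΔX_{t−1} = X_{t−1} − X_{t−2}` is the lagged abundance change, `A` maps
  changes to current abundances, and `B` maps changes to metabolite levels.
- **gLV** — generalized Lotka–Volterra ODEs,
  `dx_i/dt = x_i (μ_i + Σ_j M_ij x_j)`.
- **CR** — MacArthur consumer–resource ODEs with linear uptake.

**Impute** missing observations with per-variable Gaussian-process
regression over time (RBF or Matérn-3/2 kernel plus fitted noise),
returning means and predictive bands at any level.

**Infer** interaction matrices by per-equation least squares (OLS/ridge,
gradient matching for gLV) or Bayesian ensemble MCMC with configurable
priors: Normal on coefficients and intercepts, an optional horseshoe for
sparse networks, half-Normal noise scales, and an optional LKJ prior on
residual correlations (on by default for MVAR). Posteriors come back as
ArviZ `InferenceData` with R-hat/ESS diagnostics, point estimates, and
equal-tailed credible intervals; AIC/BIC support model comparison.

**Classify stability**: a discrete-time interaction matrix is stable when
all eigenvalues have modulus < 1 (strictly). `posterior_stability` applies
the criterion to every posterior draw and, independently, to the
element-wise posterior-median matrix, reporting the percentage of stable
draws.

## Worked example

Recover a known interaction matrix from noisy simulations
(`examples/var_recovery.py`):

```python
import numpy as np
from microdyn import generate_fixture, infer_var_bayes

params, series = generate_fixture(
    "var", n_vars=3, n_steps=200, seed=0, noise_sd=1.5, stability="stable"
)
post = infer_var_bayes(series, seed=1)
print(np.round(post.median("A"), 3))
print(round(float(np.median(post.stacked("noise_sd"))), 3))
```

prints

```
[[-0.103  0.494  0.131]
 [-0.431  0.269  0.903]
 [ 0.614 -0.432 -0.882]]
1.479
```

against a true matrix of

```
[[-0.098  0.476  0.078]
 [-0.398  0.269  0.969]
 [ 0.704 -0.523 -0.941]]
```

i.e. every posterior-median coefficient lands close to the value that
generated the data, the truth sits inside the 95% credible intervals, and
the noise standard deviation used in the simulation (1.5) is recovered as
1.479. The other scripts in `examples/` walk through simulation of all four
model families, GP imputation, species–metabolite (MVAR) inference with
posterior stability analysis, and AIC/BIC model comparison.

## Command line

A thin CLI wraps the same library calls:

```bash
microdyn simulate var --seed 3 --out series.csv
microdyn impute --input series.csv --seed 2 --out imputed.csv --bands bands.csv
microdyn infer mvar --input imputed.csv --seed 7 --out posterior.nc
microdyn stability --posterior posterior.nc --matrix A --out report.json
microdyn pipeline --config cfg.yaml --input series.csv --out-dir results/
```

Time series travel as tidy CSV (a `time` column, one column per variable,
empty cells for missing values) with a sidecar JSON recording which columns
are taxa and which are metabolites. Every stochastic command requires an
explicit seed, and `pipeline` writes a provenance record (config hash,
stage seeds, versions) beside its outputs.

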