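# Methods

This note documents the models, priors, synthetic-data design, sampler and
numerical choices behind `vaxsae`, and what the synthetic experiments do
and do not demonstrate.

## Problem

National household surveys (DHS-style) measure child vaccination status in
a stratified two-stage cluster design: within each district, urban and
rural strata are sampled, clusters (enumeration areas) are drawn with
probability proportional to size, and ~10–30 children aged 12–23 months
are surveyed per cluster. Direct design-based estimates of district
coverage are unbiased but noisy where data are sparse. Small-area models
borrow strength — either across the district adjacency graph (discrete
models) or through a continuous spatial field fitted to geolocated cluster
data (geostatistical models). The package implements both families plus
the evaluation harness that compares them.

## Models

All linear predictors are on the logit scale with an intercept and
optional covariates.

**Discrete family** (`vaxsae.discrete`): shared spatial effect
`phi ~ N(0, sigma_phi^2 Q(W)^{-1})` with the Leroux precision
`Q(W) = rho (diag(W 1) - W) + (1 - rho) I`; `rho = 0` is an iid effect,
`rho = 1` the (improper) intrinsic CAR. Likelihoods:

| model | data | likelihood |
|---|---|---|
| D-UNWB | raw district counts | `Y_i ~ Binomial(N_i, expit(eta_i))` |
| D-LN | empirical logit of the direct estimate | `Y_L,i ~ N(eta_i, var_Y,i)`, variance known |
| D-ESS | effective counts | `Y_E,i ~ Binomial(N_E,i, expit(eta_i))`, continuous |

Priors: `beta ~ N(0, 1e6)` per coefficient; `logit(rho) ~ N(0, 0.45)`
(we read the 0.45 as a variance — the common parameterization in the
areal-smoothing literature; the prior is weak either way);
`sigma_phi^{-2} ~ Gamma(0.1, 0.1)`. Non-integer effective counts use the
gamma-normalized continuous binomial log-likelihood, preserving gradient
smoothness. Districts with boundary direct estimates (`p in {0, 1}`,
undefined transform variance) carry no likelihood term; because the joint
sampler always draws their `phi`, their coverage draws are exactly the
posterior predictive under the model. Covariates are standardized
internally and coefficients back-transformed in the output (coverage
estimates are invariant to this).

**Continuous family** (`vaxsae.continuous`): cluster counts
`Y(s) ~ Binomial(N(s), expit(x(s)'beta + omega(s) [+ eps(s)]))` where
`omega` is a stationary Gaussian process with Matérn covariance at
smoothness `nu = 1` (fixed for identifiability), marginal variance
`sigma_omega^2` and practical range `r = sqrt(8)/kappa` (the distance at
which correlation falls to `sqrt(8) K_1(sqrt(8)) ~ 0.14`, "close to
0.1"). C-GPIID adds the iid nugget `eps` (variance `sigma_eps^2`,
between-cluster excess variation); C-GP omits it. Hyperpriors are
penalized-complexity: the joint PC prior for a 2-D Matérn field,
`pi(r, sigma) = lambda_r lambda_s r^{-2} exp(-lambda_r/r - lambda_s sigma)`,
calibrated by `P(r < r0) = 0.01` and `P(sigma_omega > 5) = 0.01`, and an
exponential PC prior with `P(sigma_eps > 5) = 0.01`. Default
`r0` = 5% of the north–south extent of the study region.

Inference is exact dense-covariance MCMC — no SPDE mesh. At the package's
design scale (≤ ~500 clusters) dense Cholesky factorizations are cheap and
keep the model exactly the one written above, which is what makes
validation against brute-force quadrature oracles meaningful.

**Prediction** (`predict_surface`): per posterior draw, `omega` at grid
centroids is drawn from the exact Gaussian conditional given `omega` at
the data locations under that draw's `(sigma_omega, r)`, then
`p_r(s) = expit(x(s)'beta_r + omega_r(s))`. The nugget is *not* added to
grid predictions: it models between-cluster noise, not a property of
locations, so the predicted surface is the spatially structured coverage.
(The alternative — marginalizing over a nugget at every grid cell — would
widen grid-level intervals but leaves population-weighted district
aggregates nearly unchanged.) Large grids are simulated in
district-sized blocks, each conditioned on all data; this drops the
posterior noise correlation *between* blocks, which is irrelevant for the
within-district aggregates the pipeline reports.

## Design-based layer

Weights are normalized per district so per-child weights sum to the
district's surveyed children. The direct estimate is the
Horvitz–Thompson ratio over individuals; its variance is the stratified,
with-replacement, between-PSU Taylor-linearized estimator with clusters as
PSUs (no finite-population correction). Single-PSU strata are collapsed
with the district's other stratum, mirroring common survey-software
behaviour; a district with a single cluster has undefined variance and is
flagged missing rather than patched. The empirical logit and effective
sample size follow from `p_hat` and `var_p`; boundary and zero-variance
districts are flagged missing and imputed by the models'
posterior predictives.

## Synthetic country

The generator (`vaxsae.synthetic`) emulates the structure the models
assume, not any particular country:

* **Districts**: Voronoi cells of uniformly random seeds clipped to the
  rectangle (irregular adjacency graphs like real admin maps); adjacency =
  shared border of positive length. Coordinates are planar km; all
  distances Euclidean.
* **Grid**: regular cells (default 5 km); each centroid assigned to the
  district covering it, border ties going to the smaller district id.
* **Population**: a log-Gaussian field (Matérn draw on a coarse lattice,
  bilinearly interpolated, exponentiated), normalized within district to
  shares `q(s)`. The urban stratum is the top 20% of cells by population
  within each district (configurable quantile).
* **Truth**: `omega` drawn by exact Cholesky of the dense Matérn
  covariance over grid centroids; `p_true = expit(X beta + omega)`.
  Practical up to roughly 5,000 cells; the nugget is applied only at
  cluster level, never to the grid truth.
* **Survey**: clusters allocated to districts proportional to population
  (≥ 2 each, capped by cell counts), split urban/rural with urban
  oversampled (default 35% of clusters from the ~20% urban cells),
  sampled without replacement with probability proportional to cell
  population; design weight = 1 / (n_h pop_k / pop_h). Counts
  `Y ~ Binomial(N, expit(logit p_true + eps))` with `eps ~ N(0,
  nugget_sd^2)`; `N` is redrawn until ≥ 2 (surveys exclude single-child
  clusters).

Default study conditions: 25 districts on 350 × 350 km, 300 clusters,
10–30 children per cluster, latent field `sigma_omega = 0.6`,
`r = 150` km, `beta = (0.5, 0.4)` with one smooth covariate, nugget sd
0.2 — a mid-sized district-representative survey with moderate spatial
structure. All randomness flows from one integer seed through named
substreams, so any stage can be re-run independently and every artifact
is reproducible from config + seed.

What the generator does **not** emulate: cluster coordinate displacement
(DHS jitter) and displacement-aware covariate extraction, nonresponse and
weight adjustments beyond inverse inclusion probability, multiple survey
rounds, and real covariate measurement error. Passing tests therefore
demonstrate correctness of the estimators and samplers under the models'
own assumptions — not robustness to the messiness of real DHS microdata.

## Sampler

All five models share one Gibbs scheme (`vaxsae.mcmc`) on a whitened
state: latent block `u = (beta, z)` with `phi = sigma_phi A(rho) z`
(eigendecomposition of the graph Laplacian) or
`omega = sigma_omega L(r) z` (Cholesky of the Matérn correlation), plus
unconstrained hyperparameters.

1. **Latents**: Hamiltonian Monte Carlo with hand-coded gradients,
   dual-averaging step-size adaptation (target acceptance 0.8) and
   diagonal mass estimation during warmup.
2. **Hyperparameters**: coordinate-wise adaptive random-walk Metropolis in
   the whitened (non-centered) parameterization, where the latent prior is
   invariant and only the likelihood and hyperprior enter the ratio.
3. **Interleaved centered move (ASIS)**: a second Metropolis sweep that
   holds the *natural-scale* field fixed, so the likelihood cancels and
   the ratio involves only the field prior and hyperprior; the state is
   re-whitened on acceptance. Interleaving the two parameterizations is
   what makes the scale and range parameters mix well regardless of how
   informative the data are.

Defaults: 4 chains, 1000 warmup + 1000 kept draws; split-R-hat and bulk
ESS (via ArviZ) on all scalar parameters, with `converged = False` when
any R-hat ≥ 1.01 (the fit is returned either way). The cross-validation
harness uses shorter chains (2 × (400 + 400) discrete, 2 × (250 + 250)
continuous, 100 surface draws) — posterior means and CRPS at the
tolerances of interest stabilize well before full-length chains, and the
leave-one-district-out loop runs 125 fits.

Correctness is established against independent brute-force oracles
(`tests/oracles.py`): dense-grid integration of the exact joint posteriors
of small model instances, parameterized in whitened latent coordinates
with the vague intercept absorbed into a likelihood-bounded offset so the
integrand stays smooth and bounded for every hyperparameter value
(a naive grid over the field itself cannot resolve the prior ridge at
large range / rho near 1 and silently biases the answer — we verified the
resolved version against the sampler from both directions, and
resolution-doubling moves the oracle values by < 2e-4). Posterior means
of coverage agree with the oracles within 0.01.

## Numerical choices

* Matérn correlation inside MCMC loops is evaluated from a precomputed
  65,536-node linear interpolant of `x K_1(x)` (absolute error < 1e-6,
  verified in tests); the public `matern_covariance` uses
  `scipy.special.kv` exactly.
* Cholesky factorizations use an escalating jitter schedule
  (1e-8 → 1e-4 of the diagonal scale); conditional covariances in
  prediction are formed on the correlation scale and fall back to
  eigenvalue clipping (nearest-PSD projection) when near-singular
  interpolation systems leave ~1e-4 floating-point debris.
* `logit(rho)` grids / whitening treat a Leroux spectrum value below
  1e-10 as singular (the intrinsic limit).
* Kriging of cluster covariates to the grid (`krige_covariate`) is
  ordinary kriging with an exponential covariance and no nugget (exact
  interpolation), range = first quartile of pairwise inter-cluster
  distances; proportions are interpolated on the logit scale and
  back-transformed. The exponential family is an assumption — the
  covariance family behind this preprocessing step is rarely reported and
  results are insensitive to it at the ranges involved.
* CRPS uses the O(m log m) sorted identity for the Gini term; it equals
  the literal double sum to ~1e-12 (cross-checked in tests).
* Ties where a grid centroid lies exactly on a district border go to the
  smaller district id, deterministically.

## Evaluation

Leave-one-district-out: discrete models lose a district's response but
keep its covariates (prediction = posterior predictive through the CAR
structure); continuous models lose all clusters in the district and
predict its grid cells from the rest. The reference values are the direct
weighted estimates from the full data; `p_hat_i` for RBias/RMSE/MAE is the
posterior mean of held-out coverage, CRPS uses the full held-out draw set.
Districts with boundary direct estimates are excluded from metric averages
(their count is reported). The `national-mean` baseline row scores the
constant pooled direct estimate; any spatial model worth fitting should
beat it on RMSE. Exceedance probabilities `P(coverage >= t)` default to
t = 0.80 and 0.95.

## Known limitations

* Dense-covariance inference scales as O(n³) in clusters and grid block
  size; the package targets desk-scale experiments (hundreds of clusters,
  thousands of grid cells), not national 1-km rasters.
* Short-chain CV fits can leave split-R-hat above 1.01 on weakly
  identified hyperparameters; the convergence flag is carried through
  rather than enforced, and the aggregate CV metrics are insensitive to
  this at the tested scale.
* The Gamma(0.1, 0.1) precision prior and the 0.45 logit-rho variance are
  conventions, not defaults tuned here; district-level estimates are
  insensitive to them in the fixtures tested.
* `read_grid` infers covariate columns by the `x<k>` naming convention of
  the generator.
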