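# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `mackmix`.

## 1. The zero-one inflated beta regression

### Distribution

A species proportion `y ∈ [0, 1]` follows the three-part mixture

* `P(y = 0) = zoi (1 − coi)`,
* `P(y = 1) = zoi coi`,
* `y | 0 < y < 1 ~ Beta(μφ, (1 − μ)φ)` (mean–precision parameterization,
  mean `μ ∈ (0, 1)`, precision `φ > 0`).

`zoi` is the probability of any boundary value (a single-species haul);
`coi` the conditional probability that the boundary value is 1. The mean
is `zoi·coi + (1 − zoi)·μ`, and this is the quantity used to split mixed
catches downstream.

### Regression structure

All four quantities are linked to one design matrix of standardized
covariates (intercept first): logit links for `μ`, `zoi`, `coi`; log link
for `φ`. Standardization (zero mean, unit SD, training-set statistics
reused for held-out data) makes a single shrinkage scale meaningful across
covariates. A Gaussian spatial random effect `u_b ~ N(0, σ_u²)`, indexed
by the 1°×1° grid cell of the record (`block_size` configurable), enters
the `μ` predictor only: boundary inflation is already covariate-driven,
and the Beta mean is where residual spatial autocorrelation distorts the
apportionment most directly. Non-intercept coefficients carry a Laplace
prior with scale `prior_scale` (default 1.0 on the standardized scale —
weakly informative for effects of order unity).

### MAP estimation

`infer.fit_map` minimizes the negative log posterior with L-BFGS and an
analytic gradient (digamma terms for the Beta component, Bernoulli scores
for the inflation parts). Two numerical choices:

* the Laplace penalty uses the smooth surrogate `√(β² + ε²)`, `ε = 1e−8`,
  so the objective is differentiable at zero (MCMC uses the exact prior);
* `σ_u` is held fixed during MAP (default 1.0; settable via the init
  params). The joint mode of `(u, σ_u)` in a hierarchical Gaussian model
  degenerates at `σ_u → 0`, so profiling it at the mode is not meaningful;
  the posterior for `σ_u` is left to MCMC.

Standard errors come from the observed information (finite differences of
the analytic gradient, central, step `1e−5(1 + |θ|)`), inverted with a
pseudo-inverse fallback. These give the Wald intervals used in the
parameter-recovery checks.

### MCMC

`infer.fit_mcmc` is a seeded, sampler-agnostic reference implementation
built from Metropolis components (the convergence gate, not the engine, is
the contract):

* one multivariate random-walk block per coefficient vector, proposal
  shape from the MAP covariance, globally scaled toward 35% acceptance
  (Robbins–Monro batches of 50 during burn-in only); the Beta-mean block
  is swept twice per iteration, as it is the slowest of the four;
* proposal shapes are refreshed from the chain's own recent history every
  250 burn-in iterations (adaptation stops at burn-in's end, so the
  post-burn-in kernel is fixed);
* spatial effects are updated by simultaneous per-site Metropolis moves —
  the likelihood factorizes across blocks given the coefficients, so a
  product of independent site kernels is valid and costs two vectorized
  likelihood evaluations per iteration;
* a recentering move proposes `intercept += δ`, `u ← u − δ`: the
  likelihood is invariant, only the Gaussian `u`-prior changes, and the
  move walks the intercept/mean-`u` ridge that otherwise dominates the
  autocorrelation time when there are few blocks;
* `σ_u²` carries an inverse-gamma(2, 0.5) hyperprior (prior mean 0.5,
  weakly informative) and is drawn exactly from its conjugate conditional
  (Gibbs). Conjugacy is the reason for this prior choice: a random walk
  on `log σ_u` was the convergence bottleneck.

Chains start from the MAP estimate jittered by twice its standard errors.
Defaults are 4 chains × 4000 iterations with the first 2000 discarded.
Convergence is screened with the classic split Gelman–Rubin statistic
(each post-burn-in chain halved; `R̂ = √(V̂/W)`), gate 1.05; zero-variance
parameters return NaN rather than a spurious value.

### Model checking

* Posterior predictive checks: 100 replicated datasets simulated from
  randomly selected post-burn-in draws; compared statistics are the exact
  fractions of 0s and 1s, the mean, and the interior deciles, each against
  its central 95% replicated envelope.
* Cross-validation: 5 folds, blocked by spatial block by default
  (held-out locations are spatially separated; `blocking="record"` gives
  plain row folds). Refits use MAP for runtime; held-out predictions are
  the ZOIB mean with `u = 0` for unseen blocks (population-level
  prediction). Scores: RMSE, MAE, R² (1 − SS_res/SS_tot, possibly
  negative, NaN for constant responses).

### Catch splitting

`blue = p · mixed`, `chub = mixed − blue`, per-set values divide by the
haul count. A short fixed-point correction enforces `blue + chub ==
mixed` bit-exactly under round-to-nearest (the naive `a + (b − a)` is not
always `b` in floating point). Files written by the pipeline preserve
this exactness when read back with pandas' `float_precision="round_trip"`.

## 2. Environmental matching

Rasters are regular lon/lat grids of cell centres; CHLA arrives on a
coarser grid and is regridded to the fine grid by nearest neighbour
before matching. Records join to the same-day field value at the nearest
cell centre, distance measured in degree space (at these latitudes and
0.083° cells the selected cell almost never differs from great-circle
selection, and it matches grid-index tooling); exact ties go to the lower
(lat, then lon) index. Records matching only missing cells are dropped
with a logged count. The collinearity filter is iterative-greedy: while
any retained pair has `|r| ≥ 0.7`, the lower-priority member of the
worst-offending pair is dropped. The default priority (SST > Chla > SSS >
MLD > UO > VO > SSH) encodes the ecological argument that salinity
separates the two species' niches better than sea-surface height, so when
the SSS–SSH pair exceeds the threshold it is SSH that leaves.

## 3. The additive model

The response is `log(catch-per-set + 1)` — the `+1` retains zero-catch
records. Each covariate gets a cubic P-spline: **equidistant, unclamped
knots** extended three knot-spacings past the data range, basis dimension
`k = 10`, and a second-difference penalty on the coefficients. With this
construction the Greville abscissae are equally spaced, so the penalty's
null space is exactly the constant-plus-linear functions of the covariate
— heavy smoothing therefore collapses a term to a straight line rather
than to an artifact of knot placement (the reason this construction was
chosen over quantile-spaced clamped knots). Terms are centred by a
sum-to-zero-over-data constraint absorbed through a null-space
reparameterization; the model keeps an explicit intercept.

Smoothing parameters minimize the GCV score `n·RSS/(n − edf)²` via a
per-coordinate log-λ grid sweep (two passes, decade grid `10⁻⁴…10⁶`)
polished by Nelder–Mead. λ is clipped to `e^±25` (beyond that the linear
system's conditioning, not the fit, changes the answer), and GCV ties
resolve toward larger λ — this makes a noise-free linear signal, for
which GCV is flat in λ, land on the smooth limit instead of on an
interpolating fit.

Per-term edf is the trace of that term's block of the influence matrix;
Ref.df is the corresponding trace of `2F − FF`. Inference uses the
Bayesian posterior covariance `σ̂²(X'X + P)⁻¹` (not the frequentist
sandwich): it carries the smoothing bias and gives pointwise bands and
Wald-type term tests with much better null calibration (in a pure-noise
simulation, ~91% of term p-values exceed 0.05 versus ~81% with the
sandwich). P-values refer the rank-`round(edf)` quadratic form to
`F(r, n − edf)` and are approximate by nature — they are labelled as such
and are not expected to reproduce any particular published table.

The **optimal environmental range** of a species is the largest
contiguous run of grid points whose 95% band width falls in the narrowest
20% (configurable; ties prefer the run containing the curve maximum); a
flat band returns the whole grid flagged non-informative.

## 4. Centroid dynamics

Annual centroids are proportion-weighted arithmetic means of longitude
and latitude separately, in plain degree space (matching the defining
formulas); between-centroid distances use the haversine formula, since
they are reported as spatial distances in km. Weights default to the
per-record species proportion (a catch-weighted option exists via the
weight column). Uncertainty comes from a percentile bootstrap (default B
= 1000, level 95%) resampling whole records; degenerate all-zero-weight
resamples are redrawn with a capped retry. Years with fewer than 10
records are flagged, not dropped. Trends are OLS fits of centroid against
year with t-based slope inference; residual normality is screened with
the D'Agostino–Pearson omnibus and Jarque–Bera tests (scipy
implementations; both verified in the tests against independently coded
moment formulas). Constant series return a degenerate-flagged zero trend.

## 5. The synthetic-data generator

What it emulates — and deliberately does not:

* **Fields.** Seven daily covariate rasters on the 140–175°E × 30–50°N
  box. Each field is deterministic large-scale structure plus a smooth
  zero-mean random surface built from ≤3rd-order Fourier modes with
  1/(1+k²) amplitude decay (smoothness is what the spline-recovery stage
  needs). SST has a latitudinal gradient (−0.45 °C/deg) and a seasonal
  cycle peaking in late August; MLD has a winter-deep cycle whose
  amplitude is kept below its noise so the anti-phased SST–MLD
  correlation stays under the 0.7 filter threshold; CHLA is log-normal
  on a 0.25° grid (all physics variables: 0.083°). SSS is purely
  harmonic — no deterministic gradient — and SSH is built from the
  standardized SSS field plus an empirically orthogonalized residual
  surface, making their sample correlation exactly 0.72 per day
  field-wide and, because both components share the same spectrum,
  nearly scale-free: matched records see 0.71–0.73 across seeds. No real
  bathymetry, currents, vessel behaviour or gear selectivity.
* **Field days.** Fields are generated for the simulated fishing days
  (`n_days_per_year`, default 36 evenly spaced days/year) rather than
  all ~3650 calendar days; each generated day has one field per
  variable. Random streams are keyed by (seed, variable, date), so any
  subset of days regenerates identically in any order.
* **Logbook.** Per year, record positions are Gaussian about a centre
  that drifts by (0.55°E, 0.3°N) per year — the magnitudes of the
  observed north-eastward shift — truncated to the domain; mixed catch
  is log-normal (median ≈ 15 t/day, log-SD 0.7; the catch magnitude is
  independent of the environment by design); hauls are uniform on 1–5.
  Each record carries a latent proportion drawn from the ZOIB process at
  its matched standardized covariates, with spatial effects realized
  from their prior per occupied block. The default truth gives Blue
  Mackerel positive SST and SSS effects (the warm/salty preference) and
  ~30% boundary records at average conditions.
* **Sampling events.** A seeded subset of records; `n_blue ~
  Binomial(n_individuals, p_true)` with `n_individuals = 1000` (the
  stated minimum per event). Latent boundary states survive thinning as
  counts of exactly 0 or `n`, which is what keeps the inflation
  components identifiable.

Because the generator's proportions follow the fitted model family
exactly, passing recovery tests demonstrates correctness of the
machinery, not robustness to real-data misspecification (sampling-error
in proportions, preferential sampling, environment-correlated catch
magnitudes are all absent). The GAM stage illustrates the consequence:
synthetic deviance explained is ~0.2 (the log-normal catch noise is
environment-independent), well below values reported for real fisheries
data.

## 6. Pipeline and problem sizes

The pipeline (simulate → match → filter → fit → split → gam → centroids)
writes CSV/NetCDF3/JSON artifacts with a manifest of content hashes; a
stage re-runs only when its inputs, configuration or outputs changed.
NetCDF I/O uses xarray's scipy backend (classic NetCDF3) with CF-style
units and time encoding.

The test suite and the acceptance script run the study conditions at
reduced problem sizes chosen so each check completes in seconds to a few
minutes on one CPU: grids of 0.25°/0.5° over a 16–24° box, 100–150
records/year over 2014–2023, MCMC at n ≈ 900–1000 with the full
4 × 4000/2000 schedule, 20-replicate recovery batches at n = 2000. The
scaled runs keep every structural feature (boundary inflation, spatial
blocks, drift, the 0.72 collinearity pair) of the full-scale setting.

## 7. Known limitations

* The sampler is random-walk based; for models with many more covariates
  or finer spatial blocks a gradient-based sampler would scale better.
  The contract (seeded, targets the exact posterior, split-R̂ ≤ 1.05) is
  sampler-agnostic.
* GAM p-values are approximate Wald/F statistics computed after GCV
  selection; they are suitable for screening, not exact inference.
* Cross-validation refits use MAP by default; full-MCMC CV is available
  (`method="mcmc"`) but slow.
* Centroids are degree-space means; near the poles or across the
  antimeridian this would be inappropriate (the domain validator rejects
  antimeridian-crossing boxes).
* The proportion observation error of sampling events (binomial at
  n = 1000) is not propagated into the ZOIB fit; proportions enter as
  point responses.
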