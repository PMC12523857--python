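# mackmix

Splitting mixed-species mackerel catches and tracking their distributional
drift.

## The problem

Blue Mackerel (*Scomber australasicus*) and Chub Mackerel (*S. japonicus*)
co-occur on the Northwest Pacific high seas and are morphologically similar
enough that purse-seine logbooks record only a single **mixed** daily catch.
Stock assessment, however, needs species-specific abundance. `mackmix`
implements the statistical pipeline that solves this: sparse sampling
events (on-deck identification of ≥1000 individuals) give observed species
proportions; a regression of those proportions on environmental covariates
then apportions *every* logbook record, and the reconstructed
species-specific fields support response-curve and range-shift analyses.

The package is aimed at fisheries scientists and quantitative ecologists.
Because real logbooks and the matching ocean-reanalysis extractions are
proprietary, a first-class synthetic-data module generates logbooks,
sampling events, and daily gridded covariate fields with known ground
truth, so the full pipeline runs — and is tested — offline.

## The model

The daily proportion of Blue Mackerel `y ∈ [0, 1]` frequently hits the
boundaries (single-species hauls). It is modelled with a **zero-one
inflated beta (ZOIB)** mixture:

    P(y = 0) = zoi · (1 − coi)
    P(y = 1) = zoi · coi
    y | interior ∼ Beta(μφ, (1 − μ)φ)

with logit links for μ, `zoi`, `coi` and a log link for φ on a shared
design of standardized covariates (SST, Chl-a, SSS, MLD, UO, VO after a
|r| < 0.7 collinearity filter), plus a Gaussian spatial random effect on
1° grid blocks. Coefficients carry a Laplace prior; fitting is by
penalized MAP (L-BFGS, analytic gradients) and by MCMC (4 chains × 4000
iterations, 2000 burn-in) with split-R̂ convergence checks (gate 1.05),
posterior predictive checks (100 replicates), and spatially blocked 5-fold
cross-validation scored by RMSE / MAE / R².

Downstream, each record's mixed catch is split by the predicted proportion
(mass conserved bit-exactly), `log(catch-per-set + 1)` is regressed on six
penalized cubic P-splines (GCV-selected smoothing, per-term edf and
approximate p-values, "narrowest 95%-band" optimal environmental ranges),
and annual **abundance-weighted centroids**

    lon̄ = Σ lonᵢ·pᵢ / Σ pᵢ,   lat̄ = Σ latᵢ·pᵢ / Σ pᵢ

are tracked over years with percentile-bootstrap CIs, OLS trend fits
(residuals screened by omnibus and Jarque–Bera tests) and the
between-species haversine centroid-distance series.

## Worked example

```python
from mackmix import synth, zoib, infer

cfg = synth.SimConfig(
    lon_min=144, lon_max=160, lat_min=35, lat_max=48,
    n_records_per_year=120, n_days_per_year=8,
    fine_resolution=0.25, coarse_resolution=0.5, seed=7,
)
fields = synth.generate_env_fields(cfg)          # 7 vars × 80 simulated days
logbook = synth.generate_logbook(cfg, fields)    # 1200 records, latent p_true
events = synth.generate_sampling_events(logbook, 1000, 0.6, seed=11)

data, scaler = zoib.make_design(
    events, ["SST", "CHLA", "SSS", "MLD", "UO", "VO"],
    response="proportion_blue",
)
fit = infer.fit_map(data)
print(fit.wald_interval().head(3).round(3))
```

prints the first coefficients of the Beta-mean predictor with their
Wald intervals (synthetic truth: intercept 0, SST slope 0.8):

```
              estimate     se  lower  upper
b[intercept]    -0.048  0.098 -0.240  0.144
b[SST]           0.799  0.048  0.704  0.893
b[CHLA]          0.218  0.044  0.132  0.304
```

i.e. the generating SST effect (0.8) is recovered almost exactly,
confirming that warmer water raises the Blue Mackerel share.
The same objects feed `infer.fit_mcmc` → `infer.rhat`,
`infer.kfold_cv`, `gam.fit_additive` and `centroids.annual_centroids`;
the `mackmix` CLI (`mackmix run-all --config config.yaml --seed 1`)
chains all seven stages behind a YAML config with content-hash
incremental re-runs.

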