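# crashspat

Spatial analysis of road-crash injury severity for older drivers (65+),
in two stages:

1. **Hotspot identification** — a from-scratch DBSCAN over planar crash
   locations. A point p is a *core* point when its strict
   eps-neighbourhood `N_eps(p) = {q : d(p,q) < eps}` (p included) holds at
   least `min_pts` points; hotspots are the maximal density-connected sets,
   everything else is noise. A sensitivity sweep over (eps, min_pts) grids
   — e.g. radii {100, 150, 200} ft against thresholds {5, 10, 15} — supports
   parameter choice, and each hotspot is exported as a convex-hull polygon
   (GeoJSON).

2. **Severity modelling** — Bayesian binary probit and spatial lag binary
   probit. Crash i has a latent injury propensity with
   `y* = rho W y* + X beta + eps`, `eps ~ N(0, I)`, and the observed
   outcome is `y_i = 1[y*_i > 0]` (1 = injury or fatality, 0 = property
   damage only). `W` is a row-standardized k-nearest-neighbour weight
   matrix and `rho` the spatial dependence parameter (`rho = 0` reduces to
   the standard probit). Estimation is MCMC with truncated-normal data
   augmentation, a conjugate normal step for `beta`, and random-walk
   Metropolis–Hastings for `rho` on its spectral support. Models are
   compared by DIC (gaps above 10 treated as decisive), with posterior
   summaries (mean, SD, MCSE, 95% BCI) in the conventional table layout.

Because crash registries are rarely public, the package ships a
first-class synthetic generator: planted circular hotspots over uniform
background, covariates mirroring the coded category structure of the
published Nevada older-driver summary, and outcomes drawn from the exact
spatial lag probit DGP with the latent field stored as ground truth. All
estimation claims are validated against that known truth.

Intended users: road-safety researchers and spatial epidemiologists who
want a reproducible desk-scale (n up to a few thousand) reference
implementation of this workflow.

## Worked example

```python
import crashspat as cs

config = cs.SyntheticConfig(
    hotspots=[], background_count=400,
    bounding_box=(0, 0, 1000, 1000),
    covariate_schema=[cs.Continuous("driver_risk", 0.0, 1.0)],
    beta=[0.25, -1.0], rho=0.5,
    weights_spec=cs.WeightsSpec("knn", 5), seed=4)
table, truth = cs.generate_crash_table(config)
design = cs.build_design(cs.binarize_severity(table), ["driver_risk"])
W = cs.WeightsSpec("knn", 5).build(design.coords)

spatial = cs.fit_spatial_probit(design, W, cs.McmcConfig(seed=4))
print(spatial.summary())
```

prints (abridged; exact numbers from `examples/03_spatial_probit_fit.py`):

```
Parameter                          Mean   Std.Dev.       MCSE                   95%BCI
intercept                         0.258*     0.065     0.0021 (    0.132,     0.390)
driver_risk                      -0.959*     0.099     0.0039 (   -1.165,    -0.775)
rho                               0.530*     0.066     0.0035 (    0.391,     0.647)
```

The `rho` posterior (mean 0.53, 95% BCI excluding 0) recovers the true
spatial dependence of 0.5: neighbouring crashes share latent severity
risk. `driver_risk` recovers its true coefficient of −1; the star marks a
95% credible interval excluding zero. Each coefficient can also be read
through `marginal_effects`, which reports both the published-style
percentage reading (posterior mean × 100) and the conventional average
partial effect with the spatial multiplier `(I − rho W)^{-1}`.

The `examples/` directory holds one short script per capability
(simulation, hotspot sweep, model fitting/comparison, full pipeline);
each prints what it computes and what the numbers mean. A thin CLI wraps
the same pipeline: `crashspat run --out-dir out/`, with `simulate`,
`cluster`, `fit` and `compare` subcommands for individual stages.

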