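# Methods

## The problem

Older drivers (65 and over) are over-represented in severe crash
outcomes, and crash risk is spatially structured: crashes cluster along
particular corridors and intersections, and nearby crashes share
environmental conditions. The package implements a two-stage analysis:
identify *where* older-driver crashes concentrate (density clustering of
crash locations), then estimate *which factors* drive injury severity
while accounting for spatial dependence between observations (spatial
lag probit), comparing the spatial and non-spatial models by DIC.

All coordinates are planar projected units (e.g. state-plane feet);
distances are Euclidean throughout. No geodesy is performed — ingest
must supply projected coordinates.

## Density clustering (DBSCAN)

Definitions used, exactly:

* eps-neighbourhood: `N_eps(p) = {q : d(p, q) < eps}` with **strict**
  inequality, and `p` always a member of its own neighbourhood.
* core point: `|N_eps(p)| >= min_pts`, the count including p itself.
  Many libraries use `d <= eps`; this implementation deliberately keeps
  the strict form (scikit-learn agrees with it on continuous data, where
  exact-distance ties have probability zero, and is used as a
  cross-check in the tests).
* border point: non-core point inside some core point's neighbourhood;
  noise otherwise. Clusters are the maximal density-connected sets.

Algorithmics: points are scanned in index order; each unassigned core
point seeds a breadth-first expansion through the neighbourhoods of core
members. A border point reachable from cores of two clusters stays with
the first cluster discovered (deterministic index order); such ties are
recorded on the result. Neighbourhoods come from a brute-force pairwise
scan below 1,000 points and a uniform grid of cell size eps above it —
an engineering switch with identical output (tested).

The `(eps, min_pts)` sensitivity sweep runs one full clustering per grid
cell and tabulates cluster/core/noise counts; selection among settings
is left to judgment, as in practice. Hotspot footprints are convex hulls
(shapely); clusters with fewer than three non-collinear members yield
degenerate geometry and are flagged rather than dropped.

## Spatial weights

Crash observations are linked by k-nearest-neighbour weights (default
k = 5, binary, possibly asymmetric, distance ties broken by ascending
index) or by a symmetric distance band (`0 < d < threshold`, strict,
matching the neighbourhood convention). The registry behind the
published analysis never states its contiguity rule for point data; kNN
is the package default because it guarantees no isolated observations
for n > k. Distance-band isolates keep zero rows — their spatial lag is
zero — and are carried as warnings into fit reports.

Row-standardization divides each nonzero row by its sum, making the
spatial lag a neighbour average. Eigenvalues of the standardized matrix
are computed once, dense, and cached: they give the log-determinant
needed by the rho sampler and the support interval
`(1/lambda_min, 1)` on which `I - rho W` stays invertible. Dense
eigendecomposition bounds the practical scale at a few thousand
observations, which is the package's intended operating range.

## Spatial lag probit

Model: `y* = rho W y* + X beta + eps`, `eps ~ N(0, I_n)`,
`y_i = 1[y*_i > 0]`. The error variance is fixed at 1 — binary outcomes
identify coefficients only up to scale — and is deliberately not
configurable.

Sampler (LeSage-style MCMC with data augmentation):

* **Latent field.** The latent vector is multivariate normal with
  precision `P = (I - rho W)'(I - rho W)` and mean `(I - rho W)^{-1} X
  beta`, truncated orthant-wise by the outcome signs. One systematic
  single-site Gibbs scan per iteration, in fixed index order; each
  site's conditional is a univariate truncated normal. Truncated-normal
  draws use naive rejection in the bulk and Robert's shifted-exponential
  rejection in the tail (exact; moments verified against scipy out to
  30 sd). The scan is numba-compiled; its RNG is seeded from the fit
  seed, so runs are bit-reproducible. For the plain probit (`P = I`)
  the latent draws vectorize via the inverse normal CDF, with tail
  clamping at the floating-point boundary so the sign constraint holds
  exactly at every draw.
* **Coefficients.** Conjugate normal conditional: regression of
  `(I - rho W) y*` on X under a diffuse N(0, 100 I) prior (prior mean
  and scale configurable).
* **Spatial dependence.** Random-walk Metropolis–Hastings on the
  spectral support under a uniform prior; the target uses
  `ln|I - rho W| = sum_i ln(1 - rho lambda_i)` from the cached
  eigenvalues. The proposal SD starts at 0.2 and is tuned every 100
  burn-in iterations toward 30–50% acceptance, then frozen so the
  retained chain is a fixed Markov kernel. Proposals outside the
  support are rejected, which enforces the support exactly.
  `McmcConfig.fix_rho` holds rho at a given value (no M-H step); at
  `fix_rho = 0` the sampler's conditionals coincide exactly with the
  plain probit's, which is how the reduction law is tested.

Defaults: 6,000 iterations, 1,000 burn-in, thin 1 — sized so a fit at
n ≈ 400 takes a few seconds and the full validation suite runs in
minutes. Chain-half agreement and ESS were used to confirm these
defaults converge at that scale; for n in the thousands the burn-in
should be raised (the single-site scan mixes more slowly as n grows).

Summaries: posterior mean, SD, equal-tailed credible interval, and
MCSE = SD/sqrt(ESS) with ESS from arviz's autocorrelation-based
estimator. "Significant" means the 95% interval excludes zero — the
starred convention of the published tables.

### DIC

`DIC = Dbar + pD`, `pD = Dbar - Dhat`, with the Bernoulli deviance
`D = -2 sum[y ln p + (1-y) ln(1-p)]` evaluated on a thinned subsample
of draws (default ≤ 400) and at the posterior means. For the plain
probit `p_i = Phi(x_i' beta)`. For the spatial model the package uses
the exact *per-observation marginal* probability
`p_i = Phi(m_i / sigma_i)` with `m = (I - rho W)^{-1} X beta` and
`sigma_i^2 = [(I - rho W)^{-1}(I - rho W)^{-T}]_{ii}`: a composite
marginal likelihood that ignores cross-observation correlation (the
exact joint likelihood is an n-dimensional integral) but is correctly
calibrated observation by observation and reduces to the probit
deviance at rho = 0. The simpler marginal-mean plug-in `Phi(m_i)` was
evaluated and rejected: omitting the variance inflation `sigma_i > 1`
overstates confidence and degrades the spatial model's DIC so much that
it loses to the probit on strongly spatial data. Probabilities are
clamped at 1e-12 (clamp counts logged).

### Marginal effects

Two readings are reported side by side, and neither is endorsed:

* `reported_pct`: posterior-mean coefficient × 100, read as a
  percentage-point effect. This reproduces the arithmetic behind the
  published effect statements (a crash-type coefficient of −0.106
  quoted as a 10.6% decrease). It is not a conventional probit partial
  effect.
* `ape`: average partial effect `mean_i phi(eta_i) * beta_k`, averaged
  over draws; in the spatial model the total effect applies the
  multiplier `(I - rho W)^{-1}` (direct plus spillover), degenerating to
  the plain expression at rho = 0.

The published tables also print a "Marginal Variation" row that is
defined nowhere in their text; it is not reproduced here.

### Stepwise pruning

Mirrors the published protocol of removing insignificant parameters one
at a time: at each round the insignificant parameter whose interval most
clearly straddles zero — operationalized as the smallest |mean|/SD — is
dropped and the model refitted; the intercept is never removed; every
removal is logged. If everything is removed an intercept-only fit is
returned with a warning.

## Preprocessing

* Older-driver filter: age ≥ 65, inclusive.
* Severity binarization: PDO → 0; injury and fatality → 1 (fatalities
  are ~0.5% of such registries — too rare to model separately). Binary
  input passes through unchanged. NaN/"unknown" severities are dropped
  with a logged count; any other code raises, listing the record ids.
* Collinearity screen: pairwise Pearson r among candidate predictors;
  while any pair has |r| ≥ the threshold (default 0.7, a conventional
  screen — the published analysis names the test but no cutoff), the
  worst pair's later-listed member is dropped. Constant columns are
  flagged and dropped first. Fully deterministic; the report lists every
  action.
* Design assembly: intercept first, then either ordinal coding (integer
  codes as-is — the convention the published coefficient tables imply,
  one coefficient per multi-level covariate) or dummy coding (k−1
  indicators against the code-0 "Unknown" base). Ordinal is the default
  for fidelity; dummy is the statistically orthodox alternative. Row
  order, and hence the alignment between design rows and the coordinate
  list feeding W, is preserved by every operation.

## Synthetic data generator

What it emulates: (a) the clustered geography of urban crash data —
circular hotspots (uniform in a disc) over uniform background, with
true memberships recorded; (b) the coded covariate structure of the
published Nevada older-driver summary — 13 categoricals with the
printed Clark County marginal proportions (normalized percentages;
the printed raw counts are internally inconsistent for one variable)
plus total-vehicles as a rounded normal with the printed mean 1.98 and
SD 0.71, floored at 1; (c) the exact spatial lag probit outcome
process, via a dense solve of `(I - rho W) y* = X beta + eps` — exact at
desk scale — with the latent field stored so that `y = 1[y* > 0]` holds
record for record.

Default true coefficients are the published Clark County spatial-probit
posterior means (zero for covariates not retained there) with the
published intercept 1.541; the default rho is 0.5. Note the two are not
jointly calibrated: with rho = 0.5 the spatial multiplier amplifies the
mean structure, so the simulated injury share (~0.9) is higher than the
printed 63.7%; validation studies that need a realistic outcome balance
use a smaller intercept chosen to reproduce the printed share (see
below).

What it does **not** emulate, hence what passing tests do not show:
covariate dependence (columns are drawn independently; real registries
have correlated coding, e.g. weather with road surface), road-network
geometry (hotspots are discs, not corridors), temporal structure, and
measurement error in coordinates or coding. Recovery results here
demonstrate correctness of the estimation machinery, not robustness to
those real-data features.

## Validation studies (`crashspat.experiments`)

Problem sizes are desk-scale by design: n of 300–400, 5–20 replicates,
default chain lengths — the properties under test are visible at that
scale and the full suite runs in minutes. Replicate seeds derive
deterministically from one base seed.

* **Reduction law** (`null_rho_study`): data simulated at rho = 0,
  n = 400, beta = (0.5, −1). The free-rho spatial fit's rho posterior
  mean is averaged over 5 replicate datasets (a single dataset's
  posterior mean scatters with the posterior sd, ~0.13 at this n — an
  information limit of the binary model, so the replicate average is
  the meaningful bias measure). Beta agreement with the plain probit is
  checked with rho held at 0, where the two samplers' conditionals
  coincide and any difference is pure Monte Carlo error; with rho free,
  a small systematic difference of order `E[rho^2]·beta` (~0.03 here)
  remains even for a perfect sampler, and is reported but not used as a
  correctness gate.
* **Parameter recovery** (`recovery_study`): n = 400, rho = 0.5,
  beta = (1, −1), kNN k = 5, 5 seeds; posterior-mean bias and 95%
  interval coverage. At these conditions the outcome is fairly
  imbalanced (~0.88 ones) and the posterior mean shows the usual
  small-sample magnitude inflation of Bayesian probit coefficients
  (~0.1–0.2 on the intercept, vanishing by n = 1600); the bias averaged
  over seeds sits near the 0.2 acceptance band, so this study is the
  borderline one.
* **Model selection** (`dic_study`): n = 300, rho = 0.6, 20 replicates,
  beta = (0.25, −1). The intercept is anchored to reproduce the
  published injury share (~0.65): with a larger intercept the spatial
  amplification makes outcomes near-separable, both models
  near-interpolate, and DIC differences are pure noise — a degenerate
  condition unrepresentative of the published data. At the balanced
  condition DIC prefers the spatial model in ~95% of replicates with a
  mean gap of ~15.

## Known limitations

* Dense linear algebra (eigendecomposition, solves) bounds n at a few
  thousand; no sparse log-determinant updates.
* The single-site latent scan mixes slowly for large n or rho near the
  support boundary; defaults are tuned for n ≤ ~500.
* DIC uses a composite marginal likelihood; it is not the joint-model
  DIC, and pD can be slightly noisy at small deviance scales.
* Spatial error and Durbin variants, ordered/multinomial severity, and
  exact marginal-likelihood computation are out of scope.
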