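# Methods

This note documents the models, conventions and design choices behind the
pipeline, what the synthetic study system does and does not emulate, and the
known limitations.

## The virtual study system

`generate_world` builds a 200×100-cell lon/lat grid (0–20° E, 35–45° N,
6 arc-min cells ≈ 11 km) with, per scenario:

* **Monthly temperature.** tavg(m) = T_s + g·(lat − lat_s) + σ_T·Z +
  A·(1 + 0.3·Z_A)·cos(2π(m − 6)/12), with southern-edge annual mean
  T_s = 18 °C, latitudinal gradient g = −0.8 °C/° (an 8 °C north–south
  span), seasonal amplitude A = 8 °C peaking in July, and unit-variance
  correlated fields Z. tmin/tmax are tavg ∓ half a spatially modulated
  diurnal/annual spread (8 °C), so BIO2/BIO3/BIO7 are non-degenerate.
* **Precipitation.** A 60 mm/month baseline with a ±50% seasonal cycle,
  scaled by exp(0.4·Z_P + west–east log-gradient) — strictly positive and
  right-skewed, like real monthly totals.
* **Land use.** Eight fraction layers (urban, crop, range, secdn, primn,
  primf, secdf, pastr) built as a normalised composition of correlated
  log-fields plus an unassigned background, so every cell sums to < 1.
* **Terrain.** A DEM (400 ± 300 m correlated field, clipped at 0) from
  which slope/aspect are derived.

Correlated fields are Gaussian-filtered white noise with filter σ = L/2, so
the correlation function is exp(−d²/L²): the configured length L (default
10 cells) is the e-folding distance, and the semivariogram reaches
(1 − e⁻¹) of its sill at d = L. Everything is a pure function of the
config's integer seed.

Future scenarios are additive temperature shifts and multiplicative
precipitation factors (plus optional land-use transitions). The four
shipped deltas span +1.5 to +4.0 °C with ±8% precipitation — end-of-century
magnitudes for an optimistic and a pessimistic emission pathway under two
GCM-like variants. This deliberately emulates only the first-order
structure of downscaled GCM output; no spatial pattern scaling, no change
in variability or seasonality.

**Reference species.** `waspA` has a band niche: logit = 3 + 1.5·z(BIO12)
− 12·z(BIO1)² − 3·z(elevation)², centred at 13 °C annual mean / 700 mm /
400 m. Prevalence is ≈ 11% of cells — a restricted envelope, as typical for
an invader's suitable climate within a region. `waspB` is warm-limited:
logit = 2.5·z(BIO1) + 0.5·z(BIO12) − z(elev)², centred at 17 °C, i.e. only
the warm southern strip (~15% of cells) is suitable, and warming moves its
cold boundary poleward. Occurrences are drawn with cell probability
proportional to true suitability, jittered within the cell, and carry a
uniform 0–8 km coordinate uncertainty so the 5-km cleaning rule has work
to do. A multiplicative sampling-effort layer is supported but off by
default: the study design assumes unbiased sampling, which real GBIF data
do not satisfy.

**What passing tests therefore show** is that the pipeline's machinery —
metrics, thresholds, selection, ensembling, indices — is correct and that
the design recovers known niches under ideal sampling. They do not show
robustness to sampling bias, spatial autocorrelation of errors,
non-equilibrium occupancy, or dispersal limits; see Limitations.

## Occurrence preparation

Records with coordinate uncertainty strictly greater than 5 km are removed;
records with missing uncertainty are kept (absence of metadata is not
evidence of error; configurable). Thinning is randomised-greedy: visit
records in a seed-shuffled order, accept a record iff it lies ≥ 5 km (great
circle, R = 6371 km) from every accepted record. The output is maximal and
idempotent, and the 5-km figure is interpreted as the minimum pairwise
distance (the natural reading of a 5-km thinning "diameter"; the radius
reading would halve it, and the parameter is exposed).

## Predictors

The 19 bioclimatic variables follow the WorldClim conventions: BIO4 is the
population SD of monthly mean temperature × 100; BIO3 = 100·BIO2/BIO7
(0 where BIO7 = 0); quarters are 3 consecutive months with Dec–Jan
wraparound, wettest/driest ranked by precipitation total and
warmest/coldest by mean temperature, ties to the earliest quarter. Slope
and aspect use Horn's 8-neighbour stencil with cos(latitude) east–west
metre conversion; aspect is the compass bearing of the downslope direction
and flat cells carry the sentinel −1. Resampling offers bilinear, nearest
and block-mean with nodata propagation.

**Jackknife importance.** The preliminary model is a regularized logistic
fit with each predictor entering as x + x² (no interactions) — the
customary GLM formula for niche responses; a linear-only screen is blind to
band-shaped responses and misranks their drivers. Importance(p) = max(0,
CV-AUC(all) − CV-AUC(all minus p)) on four stratified folds fixed across
predictors. Collinear clusters dilute importances (proxies substitute for
an omitted driver); this is expected and is why importance feeds the
collinearity screen rather than replacing it.

**Collinearity screen.** Pairs with |Pearson r| > 0.7 (computed over all
valid land cells; zero-variance predictors are excluded with a warning)
conflict. Conflicts decompose over connected components of the conflict
graph; within a component the retained subset is the one maximising total
importance, found exhaustively for components up to 15 predictors (ties
prefer the larger subset, then the first in a fixed bit-order over sorted
names, so the result is deterministic and order-invariant). Larger
components fall back to a deterministic descending-|r| greedy that drops
the lower-importance member of the worst pair. The exact component search
is preferred because the greedy provably returns a sub-optimal subset on a
small fraction (~0.5%) of three-predictor configurations — two conflicts
sharing the most important predictor whose two neighbours are mutually
compatible and jointly more important.

## Ensemble SDM

Pseudo-absences are drawn uniformly from valid non-presence cells, n_PA =
max(1000, n_occ) (the count rule is configurable; the sentence defining it
in common protocols is ambiguous between this and other readings).
Five PA repetitions × five stratified 70/30 splits × four algorithms give
up to 100 candidates per species. The SRE is the strict BIOCLIM box over
presence minima/maxima; GLM is standardized quadratic logistic; RF and GBM
are standard tree ensembles with fixed seeds. A candidate is admitted iff
TSS > 0.6 **or** AUC > 0.8 on its held-out fold, TSS evaluated at the MSS
threshold of the fold's scores. Admitted members are combined by
TSS-weighted averaging (weights ∝ max(TSS, 0), normalised; equal weights if
all admitted TSS ≤ 0, which only the AUC branch can produce). Weighted
committee averaging is the conventional ensembling rule where none is
otherwise specified; an equal-weight alternative is a one-line config
change.

AUC is the rank-sum statistic with ties at ½; TSS = sensitivity +
specificity − 1 with presence iff score ≥ threshold. The MSS threshold
search uses the midpoints of consecutive sorted unique scores — a finite
candidate set realising every achievable confusion table — with ties broken
toward the lower threshold (favouring sensitivity).

## Binarization and range dynamics

Potential ranges use cell = 1 iff suitability ≥ threshold. The MSS
threshold is selected **once per species on current-scenario scores** at
the training presence/PA sites and applied to every projection. The
recompute-per-scenario alternative (`RunConfig.mss_per_scenario=True`) is
implemented but not the default: because pseudo-absences are treated as
absences even where future climate has become suitable, a per-scenario
threshold ratchets upward under warming and cancels genuine expansion — on
the synthetic warming experiment it collapses a true RER of ≈ 2.5 to ≈ 1.0,
while the calibrated threshold recovers ≈ 2.2. Published per-scenario MSS
tables are reproduced in spirit (thresholds vary by species; they also vary
by scenario under the optional mode).

RER = RF/RC, RSI = 2·RS/(RC + RF), expanding range = future ∖ current, all
on spherical cell areas A = R²·Δλ·(sin φ_top − sin φ_bottom). By the
Sørensen formula, RSI near 1 means the ranges coincide; the occasionally
seen verbal gloss that *low* RSI indicates similar positions inverts the
formula and is not followed here. Range centroids are area-weighted means
of unit vectors on the sphere; the shift is the great-circle distance and
initial bearing between them. The paired t-test of current vs future range
sizes is two-sided on the per-species differences and refuses zero-variance
input.

Change maps are future − current, so positive values are increases (the
convention matching reported "% of land with increasing overlap"
statements; the opposite subtraction order sometimes appears in prose).
Hotspots are the area-weighted top decile of an overlap surface; the cutoff
is reported alongside the continuous map so no information is lost.

## Orchestration and problem sizes

`run_pipeline` derives every stage seed from the config seed via
`SeedSequence`, making reruns byte-identical at the CSV level. A full
reference study (2 species, 5 scenarios, 5×5 repetitions, 200×100 grid,
600 occurrences per species) takes about a minute on one CPU; the test
suite's recovery and directional experiments repeat such runs over five
seeds each and complete in a few minutes. These sizes were chosen so that a
complete verification cycle runs interactively; grid, repetitions and
sample sizes all scale up by config if a closer emulation of a 2.5-arc-min
global study is wanted.

Species whose ensemble ends up empty (no candidate passes the gate) are
recorded as failures and the run continues — matching how a multi-species
study degrades in practice.

## Limitations

* No dispersal constraints or connectivity: potential ranges assume
  unlimited dispersal, as is conventional for invasion-risk screening.
* The synthetic generator omits sampling bias (unless an effort layer is
  supplied), observation error beyond coordinate jitter, temporal
  non-equilibrium, and interactions among species.
* Only WGS84 lon/lat grids are supported; no projected CRSs.
* The algorithm roster implements four of the commonly used ten; the
  gating/ensembling surface treats any additional adapter identically.
* Raster I/O is plain-text ESRI ASCII grid, chosen for transparency and
  diffability rather than storage efficiency.
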