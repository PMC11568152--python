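# Methods

This note documents the models, algorithms and design choices behind
`stagespec`, in the order the pipeline runs them.

## Study design model

A design is a set of circular plots (default radius 12.62 m, i.e. 500 m²)
classified by forest developmental stage (gap, establishment, optimum,
plenter, terminal) and elevational zone (submontane, montane, subalpine).
The canonical design crosses the five stages with the three zones at ten
replicates each: 150 plots. Zones are an explicit column rather than a
function of elevation, because field classifications can place plots
slightly outside the nominal 850/1400 m band edges; validation reports such
mismatches but never rewrites them. Coordinates are planar metres; tables
whose coordinates fit inside lon/lat ranges are rejected rather than
silently projected.

The generator draws plot centres around zone-specific cluster centres
(rejection-sampled until all pairwise distances exceed the 125 m spacing
floor), elevations uniformly within each zone's range (defaults 605–850,
850–1400, 1400–1725 m), sampling days uniformly in day-of-year 150–240, and
assigns `spatial_group` labels by k-means proximity clustering (about six
plots per group), mirroring how neighbouring field plots are grouped for
random intercepts. Everything is reproducible from a single seed.

## Community generator

Incidence tables come from a Dirichlet–Bernoulli occupancy model chosen as
the simplest process that *decouples* the three quantities the
specialization SES must disentangle:

* **true niche breadth** — per zone `z`, species `s` draws stage-affinity
  weights `w_sz ~ Dirichlet(κ_z · 1₅)`; small κ concentrates use on one
  stage (specialists), large κ spreads it evenly (generalists);
* **occupancy** — a per-species base rate `q_s ~ Beta` with mean equal to
  the scenario's `occupancy_rate` (default 0.25) and concentration 2, broad
  enough that realized occupancies span from singletons to near-ubiquitous
  species — reproducing the occupancy–breadth confound that motivates the
  null model in the first place;
* **richness trends** — a log-scale elevation slope (per SD of elevation)
  and a vector of per-stage multipliers (e.g. U-shaped).

Occurrence of species `s` at plot `p` (stage `i`, zone `z`) is Bernoulli
with probability `q_s · 5 · w_sz[i] · shape[i] · exp(slope · elev_z(p))`,
clipped to (0, 0.99]. The factor 5 makes `q_s` interpretable as the
occurrence probability at a preferred stage. Species that are never
realized are dropped, as in field data; the drawn weights and rates travel
with the table as ground truth for recovery tests.

What the generator deliberately does **not** emulate: spatially
autocorrelated occupancy, phenology (sampling day exists as a covariate but
does not influence occurrence), abundances, and taxon-specific richness
magnitudes beyond the species-pool size. Passing tests therefore
demonstrate that the statistical machinery recovers known structure under
these idealized conditions — not that field data meet them.

Named scenarios fix the study conditions: `null_uniform` (500 species, flat
affinities κ = 10⁶, no trends — every downstream contrast is null),
`H1_gradient` (300 species, κ = 0.2/1/5 from submontane to subalpine),
`U_shape` (250 species, gap/terminal multipliers 1.6 vs optimum 0.6,
normalized to mean 1), and `arthropod_decline` (300 species, elevation slope
ln 0.839 ≈ −17.5% per SD, an arthropod-like decline).

## Specialization SES

Niche breadth is the reciprocal Simpson index `B = 1/Σ pᵢ²` of a species'
proportional stage use within a zone, bounded by [1, 5]. Because realized
breadth grows with occupancy under any random placement, `B` is standardized
against a fixed-margin null model: the zone's species × plot matrix is
randomized holding every species' occupancy (row sums) and every plot's
richness (column sums) constant. Each of the `n_null = 500` null matrices
is generated by an independent restart from the observed matrix
(non-sequential), using the **curveball** algorithm — repeated "trades" of
the exclusive columns of two random rows — whose stationary distribution is
uniform over the fixed-margin class; a trial-swap kernel (2×2 checkerboard
swaps) is available as a cross-check. The default chain length is 5 trades
per species row, at least 1000, which empirically reproduces the enumerated
distribution on small matrices (chi-square test in the acceptance suite).
Both kernels are compiled with numba; a permutation of a 500 × 50 zone
matrix costs well under a millisecond.

`SES = −(B_obs − mean B_null)/sd B_null`; the sign flip makes larger values
mean stronger specialization. Species with zero null variation (e.g. a
species occupying every plot of the zone) carry no information and are
flagged excluded — exclusion rates of 5–15% are typical for the default
scenarios. Excluded species leave only the SES averaging; they still count
in richness and Jaccard computations. Null matrices are built per
elevational zone (plots of the zone × species observed there), matching the
per-zone definition of `B`; a `matrix_scope="pooled"` flag permutes the full
matrix instead for sensitivity analysis. Plot-level specialization averages
the SES of the non-excluded species present at each plot; plots with no
usable species are flagged missing rather than dropped silently.

## Diversity

Richness is the row sum of the incidence matrix. The beta-diversity table
contains the Jaccard dissimilarity of every unordered same-zone plot pair
with different stages (1000 pairs per full zone: C(50,2) − 5·C(10,2)),
with planar distance, |Δelevation| and |Δday| covariates. Pairs of two
empty plots have an undefined Jaccard value and are dropped with a logged
count; values of exactly 0 or 1 are kept in the table and shrunk only
inside the beta regression.

## Models and draw backends

All continuous predictors are z-transformed (mean 0, sample SD 1); the
standardization record travels with the draws so predictions can be made on
the metre scale.

* **SES model** — Gaussian location-scale: zone-specific means and
  zone-specific log-dispersions (the SES spread differs between zones).
* **Richness model** — negative binomial (NB2, log link) with a stage ×
  elevation interaction (gap baseline), optional day-of-year covariate and
  sum-coded spatial-group intercepts whose spread is reported as
  `group_sd`; fitted by maximum likelihood (statsmodels).
* **Beta-diversity model** — beta regression (logit link) with
  zone-specific means, z-scored spatial and elevational distances
  (optionally quadratic), optional day-difference, and a single precision
  φ; fitted by BFGS with the analytic score. Responses containing exact
  0/1 are shrunk by `(y·(n−1)+0.5)/n` before fitting.

Draw backends are pluggable behind the `Draws` contract:

* `bootstrap` — parametric bootstrap (simulate from the MLE, refit),
  deterministic under a seed; the reference backend.
* `laplace` — draws from the asymptotic normal approximation at the MLE;
  orders of magnitude faster and used where many fits are needed.
* `species_bootstrap` (SES model only) — resamples *species* with
  replacement within each zone and recomputes every plot mean. Plot-mean
  SES values within a zone share species, so any plot-iid sampler
  understates the uncertainty of a zone mean by a large factor; species are
  the exchangeable units behind the averages, and resampling them makes the
  zone contrasts calibrated (verified under the `null_uniform` scenario).
  The pipeline uses this backend for the SES stage.

The spatial structure of the field design is represented by grouped
intercepts rather than a Gaussian-process term: the GP is an off-the-shelf
feature of probabilistic-programming backends, its basis-function
approximation is backend-specific, and none of the package's conclusions on
synthetic data require it. No MCMC backend is bundled; the bootstrap is the
reference because it is dependency-light and seed-deterministic.

## Posterior summaries

Every coefficient or contrast vector (minimum 1000 draws) is summarized by:

* **MAP** — mode of a Gaussian-kernel density estimate (Silverman
  bandwidth, 512-point grid), clipped into the HDI if the KDE mode falls
  marginally outside; degenerate (constant) draws return the constant.
* **95% HDI** — shortest interval containing 95% of the draws (sorted
  window); cross-checked against an independent implementation in tests.
* **pd** — max(P(draw ≥ 0), P(draw ≤ 0)) ∈ [0.5, 1].
* **ROPE%** — the share of the draws *inside the 95% HDI* that fall within
  ±0.1 · SD of the modelled response; a flag switches to the full
  posterior.

Derived quantities are computed per draw and then summarized: pairwise zone
contrasts (H I, H III); the stage-averaged elevation effect — the mean over
the five stages of the elevation slope plus its stage interaction, the gap
stage contributing the bare slope — and its percent change per SD,
`(e^β − 1)·100` (H II); and the difference-of-differences (H IV): richness
is predicted per stage at the three zone-centre elevations (group
intercepts at zero, day at its mean), `d_z(s) = |pred_z(s) −
pred_z(optimum)|` per draw, and the reported contrasts are `d_submontane −
d_montane` and `d_submontane − d_subalpine` for each non-optimum stage.

## Pipeline and reproducibility

`run(RunConfig(...))` executes simulate/load → specialization → diversity →
inference and returns a schema-validated report with one table per
hypothesis, per-taxon descriptives (mean stages used, mean plot richness,
mean cross-stage Jaccard) and a provenance block (seed, config hash,
exclusion counts). The master seed is mandatory; every stage/taxon/zone RNG
stream is derived from it by BLAKE2 hashing of the label path, so adding a
taxon never perturbs another taxon's results. All random draws use numpy's
PCG64 generator except the permutation kernels, which use numba's
Mersenne-Twister state seeded per call from the caller's generator;
identical configs give byte-identical reports.

## Problem sizes and numerical choices

Test-suite and acceptance computations use the scenario defaults: 150
plots, 250–500 species, 500 null matrices per zone, 2000 draws per model,
and 20 seeds for the recovery/calibration checks. Exclusion uses a null-SD
tolerance of 1e−12 (two-pass moments keep invariant rows at numerical
zero). The NB dispersion is clipped to ≥1e−8, and its covariance falls back
to the pseudo-inverse observed information when the dispersion sits on the
boundary of the parameter space.

## Known limitations

* The species-resampling bootstrap treats species as independent; the weak
  negative coupling induced by conditioning on plot margins makes its
  intervals mildly conservative.
* The H IV difference-of-differences uses absolute values of uncertain
  quantities and is therefore upward-biased for gaps near zero; its ROPE
  percentages are small even under null conditions, so pd is the more
  informative index there.
* Beta-regression precision φ is constant across zones; the grouped
  intercepts capture spatial clustering only at the group scale.
* The generator draws plots' occupancies independently given the
  parameters; real communities violate this through species interactions
  and spatial autocorrelation, which no test here exercises.
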