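# stagespec

Habitat specialization and biodiversity along forest development and
elevation.

`stagespec` is an analysis pipeline for community ecologists working with
binary plot × species incidence data collected across **forest developmental
stages** (gap, establishment, optimum, plenter, terminal) crossed with
**elevational zones** (submontane < 850 m, montane 850–1400 m, subalpine
≥ 1400 m). It is built for testing whether habitat specialization, species
richness and beta diversity decline with elevation — the predictions of the
altitudinal-niche-breadth hypothesis — on designs of the form
5 stages × 3 zones × n replicate plots.

## What it computes

**Specialization.** For each species and zone, niche breadth is the
reciprocal Simpson index of its proportional use of the five stages,

```
B = 1 / Σᵢ pᵢ²,       pᵢ = occupied plots in stage i / total occupied plots,
```

so `B = 1` is a perfect specialist and `B = 5` perfectly even use. Raw `B`
increases with occupancy by chance alone, so it is standardized against a
fixed-margin null model: 500 independent randomizations of the zone's
species × plot matrix that keep every row and column sum (curveball
algorithm, non-sequential restarts), giving

```
SES = −(B_obs − mean(B_null)) / sd(B_null),
```

sign-flipped so larger values mean stronger specialization. Species whose
rows are invariant under the null (sd = 0) are excluded; plot-level
specialization is the mean SES of the species present at each plot.

**Richness and beta diversity.** Per-plot species richness, and the Jaccard
dissimilarity `1 − |A∩B| / |A∪B|` between every pair of same-zone plots from
different stages, with planar distance, elevation difference and sampling-day
difference as covariates.

**Inference.** Three model families — a Gaussian location-scale model for
plot SES (zone means and zone dispersions), a negative-binomial model for
richness (stage × elevation interaction, optional day covariate, grouped
intercepts), and a beta regression for Jaccard dissimilarity (zone means on
the logit scale, distance covariates). Coefficient draws come from pluggable
backends (parametric bootstrap, species-resampling bootstrap, Laplace
approximation) and are summarized by MAP, 95% highest-density interval,
probability of direction (pd), and the percentage of the 95% HDI within a
region of practical equivalence (ROPE, ±0.1 response SD). Derived contrasts
cover pairwise zone differences, the stage-averaged elevation effect and its
percent change per SD of elevation, and the "difference-of-differences" of
|stage − optimum| richness gaps across zones.

**Synthetic communities.** A Dirichlet–Bernoulli generator produces designs
and incidence tables with known ground truth: per-zone stage-affinity
concentration κ controls true niche breadth, a Beta-distributed per-species
base rate controls occupancy, and log-scale elevation slopes and per-stage
multipliers control richness trends. Named scenarios (`null_uniform`,
`H1_gradient`, `U_shape`, `arthropod_decline`) exercise each hypothesis
mechanism end-to-end.

## Worked example

```python
import stagespec as ss

report = ss.run(ss.RunConfig(seed=42, scenario="H1_gradient",
                             n_null=500, draws=2000, backend="laplace"))
for row in report.to_dict()["h1_specialization"]["H1_gradient"]:
    print(f"{row['name']:32s} MAP={row['map']:+.2f} "
          f"HDI=[{row['hdi_low']:+.2f}, {row['hdi_high']:+.2f}] "
          f"pd={row['pd']:.2f} ROPE%={row['rope_pct']:.0f}")
```

prints

```
SES submontane - montane         MAP=+0.79 HDI=[+0.31, +1.17] pd=1.00 ROPE%=0
SES submontane - subalpine       MAP=+2.45 HDI=[+1.99, +2.88] pd=1.00 ROPE%=0
SES montane - subalpine          MAP=+1.75 HDI=[+1.18, +2.21] pd=1.00 ROPE%=0
```

The `H1_gradient` scenario generates communities whose stage-affinity
concentration rises from submontane (specialists, κ = 0.2) to subalpine
(generalists, κ = 5), and the pipeline recovers it: every zone contrast of
mean plot specialization is positive with pd = 1.00 and 0% of the HDI in the
ROPE — specialization declines with elevation, and most strongly between the
submontane and subalpine zones. The same report carries the richness
(H II), beta-diversity (H III) and difference-of-differences (H IV) tables,
plus per-taxon descriptives (here 3.2 stages used per species on average,
mean plot richness 66, mean cross-stage Jaccard 0.78) and exclusion counts
(83 of 767 species × zone records lost to zero null variation).

The same stages are available from the shell:

```bash
stagespec simulate --scenario H1_gradient --seed 42 --out sim/
stagespec specialize --plots sim/plots.csv --incidence sim/incidence_H1_gradient.csv \
    --zone all --n-null 500 --seed 7 --out ses.csv
stagespec run --scenario H1_gradient --seed 42 --out results/
```

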