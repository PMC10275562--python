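# Methods

## Overview

`evospeed` tests whether temperature-dependent evolutionary speed can be
detected from multidimensional biodiversity patterns.  It couples

1. a **synthetic dynamic landscape** (gridded temperature / aridity /
   elevation / habitability through time),
2. a **spatially explicit eco-evolutionary simulator** in which speciation and
   extinction are emergent, with four competing population-divergence models
   (M0 time-only, M1 temperature-dependent, M2 body-size-dependent, M3 both),
3. a **summary-statistic suite** condensing each simulated clade into ~40
   named statistics spanning four categories (phylogenetic tip-metric
   correlations, spatial assemblage correlations, trait distributions, tree
   size/shape),
4. a **Sobol experiment design** running every sampled parameter set under
   all four models, and
5. a **classifier ensemble** (seven algorithm families) whose per-clade class
   probabilities, weighted by holdout Cohen's kappa, yield model-averaged
   support for M0-M3 — plus a traditional **meta-analytic baseline** pooling
   Fisher-transformed Spearman correlations across clades with random
   effects.

## The landscape generator

The simulation domain emulates the structure of Cenozoic paleoclimate
reconstructions without using any external data.  Raw temperature at a cell
is

```
T_raw = cos(latitude) * G(t) + A(t) - 6.5 * elevation_km
```

where `G(t)` is the equator-to-pole gradient steepness (default rising
25 → 45 degrees over the run, mimicking the steepening gradient as climate
cooled), `A(t)` a global anomaly (default `8*(1-s)^1.5 + 1.2*sin(2*pi*5*s)`,
a hothouse-to-icehouse cooling trend with five superimposed climate cycles),
and 6.5 degrees/km the standard atmospheric lapse rate.  Aridity is 1 inside
the subtropical belt rows (|latitude| 15-35 degrees) and 0 elsewhere.  Both
fields are standardized to [0, 1] with bounds taken **jointly over all time
steps**, so the global temperature curve survives standardization (per-step
bounds would erase it).  A constant raw field standardizes to 0.5 by
convention.

**Habitability and geography.**  The world is not all land: a smooth random
field's upper quantile defines landmasses (default land fraction 0.28,
correlation length 0.8 cells), giving an archipelago-continent mosaic, and a
static random elevation field (smoothed positive Gaussian relief, scale
2.5 km) puts mountain barriers on the land.  Ocean cells are non-habitable
and carry NaN.  This matters scientifically: allopatric speciation requires
geographic isolation, and on a fully habitable grid occupied ranges percolate
into a single connected cluster, so no divergence ever accrues.  Dispersal
barriers — ocean gaps wider than the dispersal kernel and mountains whose
lapse-rate-cooled summits are thermally lethal to lowland populations — are
what allow population clusters to diverge.  `land_fraction=1` restores an
all-land world for controlled unit tests.

Default grid and timeline (36 rows x 18 columns of 220-km cells, 120 steps
of 170 kyr) are the package's desk-scale study conditions; they were chosen
once so that the sampled parameter ranges consistently generate clades in
the 20-6000-species window that defines a "complete" simulation.  All
stochastic elements derive from explicit seeds; generation is
bit-reproducible.

## The simulator

Each time step applies, in a fixed documented order: (1) bounded Brownian
trait evolution, (2) dispersal, (3) geographic clustering, (4) divergence
update, (5) speciation, (6) abundance, (7) extirpation, (8) extinction
cleanup.  Coalescence is applied within phase 4, after the clustering of the
current step.

**Abundance.**  Site carrying capacity declines exponentially with aridity,
`K = Kc * exp(-A_j)` with `Kc = 30,000` individuals.  A population's
abundance is a Gaussian thermal-suitability function,
`N = K * exp(-((T_i - T_j)/omega)^2)`; when a site's summed abundance
exceeds `K`, all populations are rescaled proportionally so the total equals
`K` (zero-sum competition).  Populations go extinct deterministically at
zero abundance and stochastically with probability
`1/(1 + exp(-mu_d*(mu_t - N)))` (defaults `mu_t = 500` individuals,
`mu_d = 0.01`; these extirpation constants are package choices exposed in
config).

**Dispersal.**  Each species may colonize habitable unoccupied cells within a
capped search radius (the 0.999 quantile of the kernel, error < 0.1% of the
colonization mass).  For each candidate cell a Weibull(shape 2.5, scale phi)
distance is drawn; colonization succeeds when the draw reaches the planar
distance to the nearest occupied cell, whose population provides the founder
traits and cluster membership.  Distances are planar Euclidean between cell
centroids on the equal-area grid (no wraparound by default; a config flag
enables cylindrical wrap).

**Traits.**  Thermal optimum and body size evolve per population as bounded
Brownian motion on [0, 1] (independent Normal(0, sigma) kicks, reflection at
the bounds; truncation available by config).  Reflection is the default
because it preserves the step-size distribution near the bounds.

**Divergence and speciation.**  Populations are grouped into clusters by
geographic connectivity (sites linked within a contact distance, default the
kernel mean `phi * Gamma(1 + 1/psi)`).  Clusters inherit identity through
time: when a cluster fragments, the fragments start diverging from zero
while inheriting their parent's divergence to third clusters.  Isolated
cluster pairs accrue divergence `g` per step:

| model | increment |
|---|---|
| M0 | `g0`, one draw from U(0.01, 1) per simulation |
| M1 | `((T1 + T2)/2)^lambda`, `T` = mean range temperature |
| M2 | `(((1-B1) + (1-B2))/2)^lambda`, `B` = mean body size |
| M3 | `((BT1 + BT2)/2)^lambda`, `BT = ((1-B) + T)/2` |

Pairs back in contact coalesce at 1 divergence unit per step (floored at
zero) and merge when they reach zero; a merged cluster's divergence to third
clusters is the unweighted mean of its constituents' values (min/max
available by config).  When any pairwise divergence reaches the threshold
`S`, the species splits along the connected components of the "divergence
below S" graph; the component with the largest occupied-cell count keeps the
parent identity (ties to the lowest cluster label).  Interpreting M0's
uniform draw as one constant per simulation makes M0 a rate-matched null
whose increment, like M1-M3's, is constant given the state; the literal
per-step reading is available as `m0_draw="per_step"`.

**Initialization and completion.**  A run starts from one ancestral species
in the habitable cell nearest the equator, thermal optimum equal to that
cell's temperature, body size 0.5.  A run is *complete* iff it finishes with
extant richness in [20, 6000].  Runs are bit-reproducible from
`(params.seed, landscape)`.

## Summary statistics

Tip metrics: ES (equal splits; pendant edge undivided, contribution halved
at each split toward the root), DR = 1/ES (a speciation-rate proxy), ED
(fair proportion) and MRD.  MRD is the topological root distance counted as
the number of edges on the root-to-tip path (so both tips of a two-tip tree
have MRD 1); conventions differ in the literature, so this is pinned by
tests.  Assemblage metrics per cell: richness, PD (spanning subtree length
including the root), MPD, MNTD, body-size mean/SD; divergence-based metrics
need at least two species and missing cells are excluded pairwise.  Spearman
correlations (average ranks for ties) connect tip metrics with species
traits and assemblage metrics with temperature and absolute latitude —
absolute latitude because the gradients of interest are symmetric about the
equator.  Trait distributions use the adjusted Fisher-Pearson skewness and
bias-corrected excess kurtosis.  Tree shape: Pybus-Harvey gamma (requires an
ultrametric tree with >= 3 tips) and the Sackin index reported as mean tip
depth.  The full vector has 43 named statistics covering all four
categories; collinearity pruning (greedy elimination of |Pearson r| > 0.90
pairs, dropping the member with the larger mean absolute correlation,
alphabetical tie-break) is provided as a separate, deterministic step.

## Experiment design and model selection

The six varied parameters (S, lambda, omega, sigma_B, sigma_T, phi) are
sampled with a plain (unscrambled) Sobol sequence mapped into their ranges;
the all-zeros origin point is skipped.  Per-run seeds are SHA-256 hashes of
(base seed, parameter id, model), collision-checked.  Only parameter sets
complete under **all four** models enter the classifier table, which
guarantees equal class sizes.

Seven algorithm families (linear discriminant, decision tree, random forest,
gradient boosting, Gaussian naive Bayes, support-vector machine with
probability outputs, multilayer perceptron) are tuned by repeated stratified
k-fold cross-validation on a stratified two-thirds training split and
evaluated on the untouched third.  Features are imputed with training-split
medians and standardized with training-split statistics.  Permutation
importance is the common importance currency across the heterogeneous
algorithms (native importances are not comparable), scaled to [0, 100] and
combined by kappa-weighted mean.  Model support for a new clade is the
kappa-weighted mean of the per-algorithm class-probability vectors, with
negative kappas floored at zero (an algorithm worse than chance should not
invert support) and probabilities rather than hard votes averaged.

## Meta-analytic baseline

Per clade (>= 20 species), Spearman's rho for the four key correlations is
Fisher-transformed (`z = atanh(rho)`, `var = 1/(n-3)`; |rho| = 1 clipped to
1 - 1e-6).  Random-effects pooling estimates tau^2 by iterative REML
(fixed-point updates, tolerance 1e-10, at most 100 iterations;
DerSimonian-Laird as fallback and as a config option), weights
`1/(v_i + tau^2)`, and a normal reference distribution for the pooled z —
pooling is on the z scale with back-transformation for reporting.

## Numerical and design choices

- Standardization bounds are global across steps; constant fields map to 0.5.
- Elevation and continents are static (no plate tectonics, no ice mask).
- The landscape realization is fixed per campaign (one "Earth"), matching the
  practice of running all simulations on a single paleo-reconstruction.
- Components/cluster labels are assigned in deterministic index order;
  species are iterated in sorted-id order so runs are reproducible.
- Dispersal search is capped at the 0.999 kernel quantile.
- Founders inherit source-population traits exactly (no founder mutation).
- The extant-tree Newick export prunes extinct tips and suppresses
  unifurcations; branch lengths are in time steps (multiply by dt to get
  absolute time).

## Problem sizes

Default experiments use a 36 x 18 grid with 120 time steps; the end-to-end
recovery experiment runs 144 Sobol parameter sets x 4 models with 3-fold
cross-validation repeated twice for classifier tuning.  These sizes keep a
full campaign on a single CPU within minutes while leaving enough completed
runs (a few dozen parameter sets) to train and test the classifier with
meaningful binomial power.  Full-scale campaigns (hundreds of parameter
sets, ~400 steps, a global grid) use the same code paths with different
configuration.

## What the synthetic data do and do not show

The generator reproduces the *structural* features the inference relies on —
a latitudinal energy gradient that steepens through time, global temperature
fluctuation, topographic cooling, subtropical aridity, and fragmented
geography — but not the actual geography or climate history of the Earth, no
plate motion, no ice sheets, and no empirical species data.  Passing tests
therefore demonstrate that the pipeline can recover a known divergence model
from simulated biodiversity patterns under these conditions; they do not by
themselves establish what real tetrapod data would support.  Because only
120 time steps are simulated, the slow-diverging body-size model (M2)
completes the 20-species threshold less often than the other models
(its per-step increment at the initial body size 0.5 is `0.5^lambda`), so
completeness filtering retains a minority of parameter sets; the same
filtering step exists at full scale for the same reason.

## Known limitations

- The full-grid distance matrix is O(cells^2) memory; fine to ~5000 cells,
  above that a tiled implementation would be needed.
- No within-cluster gene flow, no population-size feedback on divergence.
- Gamma on non-ultrametric trees is computed on node heights as-is and only
  flagged with a warning.
- The classifier table at desk scale is small (tens of rows); holdout
  metrics carry wide binomial uncertainty and the acceptance experiment
  tests only "above chance", not the full-scale accuracy band.
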