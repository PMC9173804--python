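# Methods

This note documents the models implemented in `paleoniche`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Spatial lattice and presence rasterization

The study window is a regular longitude/latitude grid (default 0.1° cells),
indexed row-major from the north-west corner; cells are half-open
[lon, lon+Δ) × (lat−Δ, lat]. All distances are great-circle on a sphere of
radius 6,371 km. A cell is a presence when its **center** lies within the
20-km buffer of at least one camp — cell-center membership is the simplest
testable reading of a buffer zone, and buffered areas are unioned so
overlapping camps never double-count. Water cells are never presences, even
inside a buffer. The grid's land mask is user-supplied: the total cell count
of any particular study region depends on a coastline/water mask that the
package does not ship.

Rasters travel as NetCDF (an `age_bp`-indexed stack with the grid's bounds
and cell size in attributes); tables as CSV; fitted models as JSON. NetCDF
is the package's single raster format — it round-trips the full stack plus
grid metadata through `xarray` with no external geospatial dependencies.

## Niche model

`maxent_like` mode implements the documented equivalence between MaxEnt and
an L1-penalised logistic (presence vs. background) model over an expanded
feature basis: linear, quadratic, pairwise-product, forward and reverse
hinge, threshold, and categorical-indicator features. Continuous predictors
are min-max scaled on the training data; hinge/threshold knots sit at the
interior deciles of the scaled training distribution (5 knots by default,
configurable). The penalty weight (`regularization`, default 1.0 in the
scikit-learn `C = 1/regularization` parameterisation) is the single knob
protecting against overfitting; as it grows without bound all feature
weights shrink to zero and the output becomes constant. Bit-compatibility
with the Java MaxEnt implementation is not claimed, and is not needed for
any property this package tests.

The background sample is uniform over non-presence land cells, 10,000 cells
or all available if fewer, seeded. Training extremes of every predictor are
stored as **clamp ranges**; projection clips incoming predictor values into
these ranges before feature evaluation, so responses extrapolate flat beyond
the training envelope. Unseen categorical levels snap to the nearest trained
level (the categorical analogue of clamping) and are logged.

`favorability_glm` mode fits an unpenalised binomial GLM (linear + quadratic
features; the full basis invites separation in an unpenalised fit) on
presence/absence over all land cells and passes its probability through the
favorability transform F = (P/(1−P)) / (n₁/n₀ + P/(1−P)), which maps the
training prevalence to exactly 0.5 and is strictly increasing in P.

**Thresholding.** τ maximises sensitivity + specificity with the rule
score ≥ τ ⇒ presence, searching the observed scores plus {0, 1} and breaking
ties toward the smallest candidate.

**Validation.** Repeated random 80/20 splits at the cell level (500 repeats
in the full protocol; the test suite and acceptance script use 5–50 repeats,
which is ample for the properties they check). Each repeat refits, sets τ on
the training fold, and scores the held-out fold: rank-based (Mann–Whitney)
AUC, Cohen's κ, sensitivity, specificity; TSS = sensitivity + specificity − 1
by identity. A repeat whose validation fold lacks a class is redrawn and
logged. Note that sensitivity on held-out data is not exactly 1 even for
separable continuous data: τ is an observed training score, and a held-out
presence can fall just below it. The degenerate-data identity (AUC = TSS = 1)
holds when scores are constant within classes.

`select07` drops, from every predictor pair with |Pearson r| ≥ 0.7, the
member with lower univariate explained deviance (binomial GLM D²),
processing the strongest remaining pair first and iterating until no pair
offends. Constant predictors are dropped with a warning.

## Paleo-projection

Projection is clamp-then-score per slice; binarization is value ≥ τ (the
boundary rule is a package choice; it makes binarized maps nest monotonically
in τ). Slices missing a model predictor are skipped with a logged gap rather
than interpolated. The range series reports the presence-cell count PP_T per
age and its mean over ages.

## Density and metapopulation

Camp population sizes are summed per cell; cells above the Tukey upper fence
Q3 + 1.5·(Q3−Q1) are removed (upper fence only — small camps are data, not
outliers; quartiles by linear interpolation, the type-7 convention). OLS
gives the slope b with its t-test. Because suitability bounds density from
above (a wedge-shaped cloud), linear quantile regressions at the 50th–99th
percentiles trace the upper envelope; R1(q) = 1 − Vfit/Vnull with V the
minimised check loss and Vnull from the intercept-only fit.

Per-cell potential population size uses the centered anchoring
PPS_c = max(0, P̄ + b·(s_c − s̄)), where P̄ and s̄ are the mean observed cell
population and mean suitability of observed cells. The source procedure
names both the observed mean and the slope without stating their
combination; the centered form uses both and reproduces the observed mean at
the observed mean suitability. An intercept-based alternative (a + b·s) is
available by configuration, the anchoring used is logged, and negative PPS
is clipped at zero. Metapopulation size = GPPS·GCS/ASA with GCS = 123 km²
(0.1° cell at the equator) and ASA = 1,079 km² (average subsistence area,
taken as a given constant rather than re-derived from the 18.5-km radius,
which gives ≈1,075 km²).

## Connectivity

Predicted presence cells × 0.16 (the documented camp-per-presence-cell
ratio; round-half-up) camps are placed uniformly without replacement.
Travel time runs Dijkstra over the 8-connected cell graph; each step costs
horizontal distance divided by Tobler's speed 6·exp(−3.5·|S + 0.05|) km/h,
with slope S = rise/run in the direction of travel — so the time field is
anisotropic, and a camp's neighbors are counted on **outbound** time. E–W
step lengths shrink with cos(latitude). Water cells are impassable by
default; a fixed crossing-penalty (hours added per water cell entered) is
available because the evidence on whether major rivers acted as absolute
barriers is ambiguous. The search prunes at the cap (7 h, encoding the
34.5-km "half range" of documented forager mobility); on flat terrain the
8-connected metric exceeds straight-line distance by at most ≈8.2% (the
octile bound), which the tests verify against the closed form.

## Archaeological validation

Curation removes carbonate dates, errors above 1,000 years, dubious
stratigraphy and missing lab codes, then any record with farming indicators
(pearl millet, oil palm, iron metallurgy, pit features) or a farming
chronoculture (Neolithic, Early/Recent Iron Age); optional stricter subsets
keep lithic-bearing sites only, or drop disputed or pottery-bearing dates.
Deduplication keeps one date per 0.5° cell per time slice — the record with
the smallest age error, ties broken by id. Site ages round to the nearest
slice; exact midpoints round to the younger slice.

The statistic compares O (sites on predicted-presence cells at their own
dates) with E = Σ_T N_T·PP_T/TC via the goodness-of-fit
χ² = (O−E)²/E + ((n−O)−(n−E))²/(n−E), df = 1, and via permutation: the date
multiset is reassigned across sites without replacement, O recomputed, and
p = (1 + #{O_perm ≥ O_obs})/(n_perm + 1) — the add-one estimator that never
returns zero.

**Calibration caveat.** O is an integer count; with 100 sites its
permutation distribution has standard deviation at most 5, so individual
values carry several percent of probability mass each. The add-one estimator
counts ties as extreme, which makes the test *conservative*: in the
package's own null calibration (1,000 synthetic replicates, 100 sites, 200
permutations) the rejection rate at α = 0.05 is ≈2.7%, not 5%. The test
never exceeds its nominal level — a valid, if slightly under-powered,
construction. Exact uniformity of the p-value is unattainable for a count
statistic of this granularity under any tie-respecting estimator; users who
need tighter calibration should use more sites or a mid-p variant.

A soil-acidity confounder screen reports the maximum |Pearson r| between a
soil layer and each model predictor over land cells, passing below 0.7, and
a point-biserial correlation checks that model performance (the in-presence
indicator) is unrelated to site age.

## IBD sharing, F_ST and private allelic richness

Segments of the same individual pair and chromosome separated by ≤0.6 cM are
fused transitively. The genotype-inconsistency condition used by upstream
merge utilities needs genotype access, so it is exposed as an optional
callback hook; default merging is purely gap-based and logged as such.
Length classes are half-open — [1,5), [5,10), [10,∞) cM; sub-centimorgan
segments are discarded. A dyad is connected in a class when its block count
reaches the minimum (4 blocks for 1–5 cM, 2 otherwise, suppressing
false-positive short segments); the population-pair sharing probability
divides connected cross-population dyads by n_a·n_b. Centromere/telomere
exclusion is the caller's responsibility upstream of the segment list. When
reading refinedIBD files, genetic start positions are synthesised from
physical positions at the standard 1 cM/Mb proxy; only segment lengths
matter to the downstream statistics.

F_ST is the Weir–Cockerham (1984) variance-components estimator aggregated
as a ratio of sums across sites; sites monomorphic across both populations
are skipped, per-site components may be negative, and the aggregate may sit
slightly below zero near F_ST = 0. Missing genotypes are excluded from the
allele-copy counts.

Private allelic richness rarefies to g gene copies: allele j with N_ij of
N_i copies in population i appears in a subsample with probability
1 − C(N_i−N_ij, g)/C(N_i, g); an allele contributes to pair (A, B) the
product of its presence probabilities in A and B when it is absent from all
other populations, and totals are divided by the number of variable sites.

## Synthetic data

The generators define the test conditions; every generator is a pure
function of configuration and seed.

* **Landscape.** Environmental layers are unit-variance Gaussian random
  fields (Gaussian-smoothed white noise; a kernel of width σ gives an
  e-folding correlation length of 2σ, default 6 cells). Through time a
  layer combines a monotone mean shift (drift, default 0.15 per slice) with
  a rotation between two independent field realizations (default 0.35
  rad/slice), so both the overall climate level and *which* cells are
  favorable change — the feature of real paleoclimate that gives the
  date-permutation test its power. True suitability is logistic in the
  layers (default coefficients (2.0, −1.5), intercept −0.5). Default grid
  50×50, 10 slices, chosen so the full suite runs in about a minute.
* **Camps.** Cells sampled proportionally to true suitability; sizes
  Uniform(0, a + b·s) with b = 43.4 by default, so the upper quantile slope
  equals b — the wedge shape, by construction.
* **Sites.** In signal mode each site lands on a suitable cell of its own
  slice with probability p_suit (default 0.8), otherwise anywhere; null mode
  places sites uniformly over land regardless of suitability and feeds the
  type-I calibration.
* **Genotypes.** Balding–Nichols island model: ancestral frequencies
  Uniform(0.1, 0.9), population frequencies Beta-distributed at the
  configured F (default 0.10), genotypes binomial.
* **IBD.** Each cross-population dyad is connected in a length class with
  the configured rate; its block count is Poisson-distributed above the
  class's minimum-block threshold when connected and below it otherwise, so
  the recovered sharing probability estimates the configured rate directly.
* **DEM.** Smoothed random relief of configurable amplitude plus optional
  straight river barriers; zero amplitude yields the flat world used by the
  closed-form travel-time oracle.

What the generators do **not** emulate: real Central African geography or
coastlines, the actual paleoclimate reconstruction and its 17 bioclimatic
variables, spatial sampling bias in camp documentation, taphonomic loss in
the radiocarbon record, linkage disequilibrium and realistic IBD segment
detection noise. Passing tests therefore demonstrate that each algorithm
recovers known structure under its own assumptions — not that the original
study's empirical estimates are correct.

## Numerical conventions

Quartiles: linear interpolation (type-7). Camp-count rounding: half-up.
Threshold ties: smallest candidate. Dedupe ties: smallest error, then id.
Binarization boundary: ≥ τ. Seeds: every stochastic routine takes an
explicit seed and uses an independent `numpy` Generator.
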