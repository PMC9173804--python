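# paleoniche

A pipeline linking ecology to hunter-gatherer population dynamics: it fits a
presence/background environmental niche model to documented forager camps,
projects it across paleoclimate time slices with clamping, converts habitat
suitability into population-density and metapopulation estimates, measures
camp-to-camp connectivity by anisotropic walking time, validates the
projections against the radiocarbon record with a date-permutation test, and
summarises recent genetic connectivity from identity-by-descent (IBD)
sharing and F_ST.

It is written for quantitative ecologists, archaeologists and population
geneticists who want each of these bespoke steps as a tested, reusable
library function, exercisable end to end on synthetic data with known
ground truth.

## The models in brief

* **Niche model.** Camp locations are buffered by 20 km into presence cells
  on a 0.1° grid. A MaxEnt-style model — an L1-penalised logistic fit over
  linear, quadratic, product, hinge, threshold and categorical features — is
  trained on presences against a background sample and scores every cell
  with a suitability in [0, 1]. A favorability GLM alternative,
  F = (P/(1−P)) / (n₁/n₀ + P/(1−P)), corrects predicted probability for
  prevalence. The presence/absence threshold τ maximises sensitivity +
  specificity; skill is reported as AUC, Cohen's κ and TSS = sens + spec − 1.
* **Paleo-projection.** Predictors are clamped to their training extremes
  before the model scores each past time slice, giving a suitability map and
  a range-size series PP_T per age.
* **Density and metapopulation.** After Tukey-fence outlier removal,
  density relates to suitability by OLS and by linear quantile regression at
  the 50th–99th percentiles (the wedge's upper bound), with the R1
  goodness-of-fit measure. Metapopulation size = GPPS × GCS / ASA, where
  GPPS sums per-cell potential population sizes, GCS = 123 km² is the cell
  area and ASA = 1,079 km² the average subsistence area.
* **Connectivity.** Predicted presences × 0.16 camps are placed at random;
  travel time follows Tobler's hiking function W = 6·exp(−3.5·|S + 0.05|)
  km/h over the 8-connected cell graph with water barriers; connectivity is
  the number of other camps within a 7-hour walk.
* **Archaeological validation.** Curated hunter-gatherer ¹⁴C dates are
  compared against E_T = N_T·PP_T/TC (sites expected on suitable cells by
  chance) via a goodness-of-fit χ² and a 1,000-fold permutation of the date
  multiset across sites.
* **Genetic connectivity.** IBD segments are merged across ≤0.6 cM gaps,
  binned into 1–5 / 5–10 / >10 cM classes, and summarised as the probability
  that random individuals from two populations share qualifying segments
  (≥4 blocks for 1–5 cM, ≥2 otherwise). F_ST uses the Weir–Cockerham
  estimator; private allelic richness is rarefied by hypergeometric
  subsampling.

## Worked example

```python
import numpy as np
from paleoniche import synth, niche, projection, density
from paleoniche.grid import rasterize_presences

cfg = synth.SimConfig(seed=1)                      # 50x50 grid, 10 slices
stack, truth = synth.gen_landscape_stack(cfg)      # known logistic suitability
camps = synth.gen_camps(truth[0], 300, cfg.b_true, seed=2)

pres = rasterize_presences(camps, stack.grid, buffer_km=20)
model = niche.fit_enm(pres, stack.slice(0), background_n=1000, seed=3)
print(f"PP={pres.n_presence}  tau={model.threshold:.3f}")

rs = projection.range_series(model, stack)
print("range size per slice:", rs.presence_counts)

s = projection.project(model, stack.slice(0), stack.grid)
land = stack.grid.land_mask
est = density.metapopulation_size(s.values[land], slope=30.0,
                                  mean_observed_pop=15.0, mean_observed_suit=0.6)
print(f"metapopulation size: {est.size:.0f}")
```

Output:

```
PP=1400  tau=0.555
range size per slice: [1389, 1423, 1408, 1432, 1448, 1441, 1415, 1437, 1443, 1385]
metapopulation size: 4073
```

`PP` is the number of presence cells produced by buffering the 300 synthetic
camps; `tau` the fitted presence threshold; the range-size series counts
predicted-presence cells on each of the ten 1,000-year slices; and the
metapopulation size converts summed per-cell potential populations into a
territory-corrected census (here with an illustrative slope and anchor).

A command-line interface mirrors the library
(`paleoniche simulate|rasterize|fit|project|density|metapop|connect|validate|ibd|fst`).

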