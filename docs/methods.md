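# Methods

## Scope and model

`podomap` implements a presence/absence ensemble species-distribution model
for podoconiosis and the downstream programmatic products (binary occurrence
map, population at risk, LF overlap, implementation-unit classification).
The modelled quantity is *environmental suitability* — the probability that
a location's environment permits occurrence — not prevalence or incidence.

All spatial computation runs on regular planar grids (projected coordinates,
km; 5-km cells by convention). Row 0 is the northernmost row; cells own the
half-open box `[x0, x0+cell) × [y0, y0+cell)`, so a point on a shared edge
belongs deterministically to the cell on its right/top. Distances are
centre-to-centre Euclidean; any operation touching a nodata cell yields a
nodata cell. Geographic-degree inputs must be projected upstream —
reprojection is out of scope.

## Training data

- Survey communities are labelled endemic (1) iff confirmed cases were
  reported, else non-endemic (0). Absences from exhaustive community
  censuses are treated as true absences; both classes carry weight 1.
- Spatial deduplication is exact-coordinate (no tolerance); on conflict
  presence wins — a confirmed case cannot be negated by a second survey.
- Pseudo-absences: one point per compiled survey record, sampled uniformly
  (with replacement) over the valid cells of countries whose evidence score
  is negative, placed at cell centres (covariates are constant within a
  cell). Weights are a min–max rescaling of |score| over eligible countries
  onto [floor, 1] with a configurable floor (default 0.25): the strongest
  evidence of absence maps to 1, so confident absences count most. The
  rescaling direction and floor are this package's documented choices; the
  source methodology states only that a 0–1 rescaling was used. Weights
  enter all learners uniformly as observation weights.

## Learners

Six algorithms behind one fit/predict contract; each accepts observation
weights, returns probabilities in [0, 1], and is deterministic given its
seed (derived per run from (global seed, algorithm, replicate) via a CRC of
the algorithm name, keeping the 50-replicate loop reproducible and
parallelisable):

| algorithm | realisation | notable defaults |
|---|---|---|
| GLM | unpenalised weighted logistic regression | — |
| GAM | cubic B-spline basis (5 knots/covariate) + ridge-logistic | C = 1 |
| GBM | gradient-boosted trees | lr 0.005, depth 5, 2,500 trees |
| ANN | 1 hidden layer (8 tanh units), weighted cross-entropy, L-BFGS | L2 1e-3 |
| MARS | piecewise-linear hinge basis at quartile knots + L1 logistic | C = 1 |
| RF | random forest | 500 trees |

GBM's learning rate and interaction depth follow the tuned settings of the
methodology this package implements; its tree count (2,500) is the
conventional budget for that slow shrinkage. The GAM/MARS/ANN realisations
are light-weight equivalents built on the installed scientific stack (the
ANN is trained directly so that observation weights enter the loss); no
claim of equivalence with any other framework's internal defaults is made.
Non-GBM hyperparameters are documented defaults sized for desk-scale data.

## Ensemble

Per algorithm, `n_reps = 50` (10 in desk-scale tests) stratified random
80/20 splits; stratification keeps both classes in every test set (needed
for a defined AUC; degenerate splits are redrawn with derived seeds, bounded
retries). Held-out AUC, TSS and PCC are weighted; TSS and PCC are evaluated
at the held-out TSS-maximising threshold, the convention of ensemble
platforms in this field. Runs with AUC < 0.8 or TSS < 0.7 are disregarded
(boundary values kept). The ensemble mean is the AUC-weighted mean of member
probabilities per cell (raw AUC weights, not rescaled); per-cell bounds are
equal-tail 2.5 %/97.5 % empirical quantiles across members — distribution-
free, since the source text does not operationalise its "confidence
intervals around the mean". Member surfaces are retained because the
population-at-risk interval needs them.

## Threshold and validation

The occurrence threshold scans all distinct scores plus midpoints and
maximises sensitivity + specificity (equivalently TSS); ties break by higher
accuracy, then lower threshold. Classification at the threshold is
presence-inclusive (`>=`). Spatial-block CV tiles the extent with
`block_km` squares anchored at the grid origin; blocks receive fold labels
1..k balanced and shuffled by seed (at continental scale 2,000-km blocks
yield more than five blocks; "five folds" is read as five fold *labels*).
Each fold's models are trained on the other folds and scored on the held-out
fold; the block-CV ensemble uses the same gates and weighting. At desk
scale, spatially held-out scores are systematically lower than random-split
scores; if the gates reject every fold model, the comparison ensemble falls
back to all fold models with a logged warning so the stability comparison
(Pearson r between the two mean maps) remains defined.

## Aggregation

Population at risk per zone = Σ population over cells with binary = 1;
the 95 % interval re-computes that sum on each member's binary map and takes
2.5/97.5 quantiles (i.e., uncertainty propagates through the ensemble, not
through the lower/upper suitability rasters). Overlap with LF combines two
binary maps into {neither, a-only, b-only, both}; class populations
partition the total valid population exactly. An IU is suitable iff the
fraction of its valid cells classified suitable exceeds `min_fraction`
(default 0: any suitable cell — the permissive reading that favours not
missing potential endemic areas); `needs_mapping = suitable AND NOT mapped`.
IUs without valid cells are flagged indeterminate and excluded from
denominators. GeoJSON zones are rasterised by the cell-centre rule.
Reported share percentages are half-up rounded to one decimal at the
reporting layer only.

## Synthetic scenarios

The generator emulates the study inputs at desk scale: a 120 × 120 grid of
5-km cells (600 × 600 km), 400 survey sites, six countries subdivided into
36 IUs. Covariates are Gaussian-filtered white noise fields (σ = 8 cells),
z-scored and mapped onto realistic ranges (precipitation 0–3,000 mm,
elevation 0–3,000 masl, LST 10–40 °C, EVI 0–1, pH 4–9, clay/silt 5–60 %),
plus a distance-to-water surface derived from a thin synthetic river mask.

True suitability is a logistic combination of documented marginal-effect
shapes: a Gaussian precipitation effect peaking at 1,400 mm (inside the
1,000–1,800 mm band) and declining beyond; an elevation window elevated
between 1,000 and 2,500 masl; a decreasing pH effect crossing one half at
pH 7 (acid soils riskier); increasing clay and silt effects. Effect weights
(20/20/15/10/10) are strong, giving a sharply delimited niche in which
occurrence is near-deterministic well inside/outside the envelope — the
regime of the exhaustively surveyed communities and confidently unsuitable
pseudo-absence countries this pipeline is designed for; with soft effects no
model (including the generating one) could pass a TSS ≥ 0.7 gate, which
would misrepresent those study conditions. The intercept is calibrated by
bisection so mean suitability over valid cells hits the prevalence target
(0.45, matching the compiled database's presence share). Survey endemicity
is Bernoulli(truth); an optional sampling-bias parameter (off by default)
tilts site placement toward suitable cells to emulate preferential
surveying. Country evidence scores are 10 × (mean country suitability −
0.2), so pseudo-absences land where the disease is genuinely unlikely;
population is a log-normal smooth surface; the LF layer thresholds a
column-shifted copy of the suitability surface so all four overlap classes
occur.

What the generator does **not** emulate: real African geography and
coastlines, covariate cross-correlations (fields are generated
independently), geocoding error, reporting bias, or geodesic distances.
Passing recovery tests therefore demonstrate correctness of the machinery
and identifiability under clean conditions, not predictive skill on real
survey databases.

## Problem sizes and numerical choices

Desk-scale runs (tests and the acceptance script) use the default scenario
with 10 replicates × {GLM, GBM, RF} and 200-km blocks in 5 folds — chosen as
the smallest configuration with a non-degenerate ensemble and block
tiling; a full run completes in a few minutes on one CPU. Ties in AUC
pair-counting count one half; threshold candidates include score midpoints
so every achievable confusion table is scanned; quantile bounds use the
linear-interpolation convention of the underlying numerics library. Seeds
below 2^31 everywhere; all randomness flows from explicit generators.

## Known limitations

- Suitability is not prevalence; population at risk assumes everyone in a
  suitable cell is exposed.
- The evidence-score rescaling direction/floor and the quantile form of the
  per-cell bounds are documented interpretations of under-specified steps.
- Desk-scale block CV has few blocks, so its fold metrics are noisy and may
  sit below the quality gates (see above).
- No reprojection: inputs must share one planar grid after upstream
  preparation.
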