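# Methods

## Problem setting

Two patch classifiers process an H&E whole-slide image independently: a
tumor detector over 87.5 × 87.5 µm patches (350 × 350 px at 40×) and a
lymphocyte detector over 50 × 50 µm patches (200 × 200 px at 40×), each
emitting a rectangular grid of per-patch probabilities. `tilscape` turns
those two grids into slide-level TIL metrics and survival analyses. The
package deliberately starts *after* CNN inference: no WSI decoding and no
model training.

## Lattice alignment

Probabilities are binarized at ≥ 0.5 (positive) per patch. The two binary
grids live on incompatible pitches, so both are replicated onto their
greatest-common-divisor lattice — 12.5 µm for the 87.5/50 pair — by
nearest-source assignment with origins co-registered at the top-left
corner. Replication is exact and deterministic: every fine cell lies
wholly inside one source patch, so no boolean interpolation is needed, and
area fractions of planted regions are preserved up to a one-cell rim at
region boundaries. Model tiling truncates slide edges differently per
patch size; extents differing by at most one coarse patch per dimension
are cropped to the overlap, anything worse is an alignment error. How the
original study co-registered the two model outputs is not documented
anywhere we could find; the GCD-lattice rule is this package's design
choice and all area-ratio metrics are invariant to it for uniform cells.

## Percent infiltration and TIL class

Percent infiltration = 100 × co-positive cells / tumor cells, computed on
the fine lattice (the ratio is scale-free for uniform cells). A slide with
zero tumor cells is *flagged*, never silently scored 0. Cohort High/Low
TIL classes split around a center statistic; both mean and median appear
in the literature for this split, so the center is a parameter
(`center="mean"` default, ties assigned Low).

## Spatial feature scoring

All five features are scored on the composite map with a single
`MorphologyConfig`. Published criteria fix the two area thresholds; the
remaining knobs operationalize qualitative language and are documented
design parameters:

| parameter | default | role |
|---|---|---|
| `connectivity` | 4 | neighborhood defining "confluent" components (conservative) |
| `desert_area_frac_threshold` | 0.25 | desert = 1 iff qualifying TIL-free area ≥ 25% of tumor area (published criterion) |
| `desert_min_component_frac` | 0.01 | a TIL-free component below 1% of tumor area is speckle, not a "significant region" |
| `forest_area_frac_threshold` | 0.10 | forest = 1 iff confluent TIL area ≥ 10% of tumor area (published criterion) |
| `forest_min_component_frac` | 0.02 | "small confluent groups" tolerated at score 0 are < 2% of tumor area |
| `strength_cutoffs` | (0, 0.05, 0.15) | strength grade = number of cutoffs the infiltration (or band) fraction strictly exceeds |
| `band_width_cells` | 2 (= 25 µm) | peritumoral band depth beyond the tumor mask; 4 cells ≈ one lymphocyte patch is a natural alternative |
| `dilation_connectivity` | 8 | chebyshev metric for the band (4 = manhattan) |
| `aggregate_min_cells` / `aggregate_multifocal_min` | 5 / 2 | a distal lymphoid aggregate is ≥ 5 cells entirely beyond tumor ∪ band; "multifocal" = ≥ 2 such components |

Notes on the open edges of the published rules, resolved here:

- The desert criteria leave 10–25% of tumor area unaddressed (score 0 is
  described as ≤ 10%, score 1 as ≥ 25%). A binary score needs a single
  boundary; we score 1 iff ≥ 25% and 0 otherwise, treating the score-1
  criterion as operative.
- Strength grades 1–3 (weak/moderate/strong) are qualitative in the
  source criteria; the 5%/15% ladder is this package's quantification and
  is configurable. Only the anchored endpoints are treated as exact: zero
  infiltration ⇒ 0, and a saturated band ⇒ 3.
- The peritumoral band ("region of the invasive boundary") has no
  published width; 25 µm beyond the tumor mask is the default.
- Desert/forest area is measured against the tumor *mask* area, not the
  tumor bounding box; human scorers may have judged visually against
  either.
- "Multifocal" aggregates = at least two qualifying components; one large
  distal cluster scores 0.
- A map with no tumor cells, or whose peritumoral band is empty (tumor
  filling the grid), is excluded with a reason rather than partially
  scored.
- Desert = 1 and strength = 3 can legitimately co-occur (e.g. 25% of the
  tumor TIL-free, the remaining 75% co-positive); the rules are
  independent by design.

Connected components and morphological distance are delegated to
`scipy.ndimage`; tests verify them against flood-fill and per-cell
distance oracles.

## High-risk stratification

Indicators: intratumoral strength ≤ 1, deserts = 1, forests = 0,
peritumoral strength ≤ 1, and (when activated) aggregates = 0. The default
active set excludes aggregates, reflecting its screening out by interrater
agreement; `screen_features` recomputes the active set from data. A
patient is high-risk iff ≥ 2 active indicators fire. The profile is
monotone: firing an additional indicator can never demote a patient to
low-risk.

## Consensus and agreement

Consensus is the per-feature median across observers; with an even panel
the lower middle value keeps the consensus in the ordinal domain (the
motivating study used three raters, where the question never arises).
Fleiss' κ is implemented directly from the standard definition
κ = (P̄ − P̄e)/(1 − P̄e); when every rating falls in one category, P̄e = 1
and the ratio is undefined although agreement is perfect, so κ is
reported as 1 with a `degenerate` flag. Slides not rated by the full
panel are dropped from the κ computation, not imputed. The screening
cutoff defaults to 0.5 (κ at the cutoff is retained); the conventional
interpretation bands (0.4–0.6 moderate, ≥ 0.61 substantial) sit awkwardly
beside a hard 0.5 cutoff, so the cutoff is exposed as a parameter.

## Survival layer

The endpoint is the progression-free interval: days to progression,
recurrence, metastasis, new primary, or death without a new tumor event;
event = 0 censors at last follow-up. Kaplan–Meier estimation, the
log-rank test, and Cox proportional-hazards fits (Efron tie handling,
solver precision 1e-9) are provided by `lifelines` behind the module
surface; a self-contained Newton fit of the Breslow partial likelihood is
available for cross-checks. Percent infiltration enters Cox models
divided by its cohort standard deviation (equivalently, scaled to unit
variance — the two phrasings used in the literature describe the same
operation). Categorical covariates expand against fixed reference levels
(PAM50 LumA, stage I — the largest strata in typical breast-cancer
cohorts); rows missing a requested covariate are listwise-deleted with a
logged count. Confidence intervals are Wald on the coefficient scale,
exponentiated. Harrell's concordance counts equal-time event/censored
pairs as comparable and risk ties as 0.5. The TIL-sensitive filter keeps
ER-negative and/or PAM50 LumB/Her2 patients; records missing both labels
are unclassifiable and dropped with a logged count.

`significance_marker` reproduces the source study's star legend verbatim
(*** p<0.001, ** p<0.05, * p<0.01 — note the unusual ordering) with a
`corrected_order` option for the conventional ladder.

## Synthetic data

The generator emulates the statistical and spatial structure of classifier
output, not H&E appearance. Tumor masks are seeded unions of discs on the
87.5 µm grid (connected by construction); lymphocyte patterns are planted
on the 50 µm grid relative to the tumor. Desert and forest targets are
sized against the *fine-lattice* tumor area and grown inside lymphocyte
cells fully covered by tumor, so planted fractions survive alignment
intact. Probabilities mimic confident CNN maps: positives ~ 1 − Beta(2,8)/2
(mean 0.9), negatives ~ Beta(2,8)/2 (mean 0.1). The `jitter` parameter
(default 0.2) adds label flips with probability max(0, jitter − 0.2):
within the default margin, binarization recovers the planted pattern
exactly — so end-to-end recovery tests isolate the alignment-and-scoring
path — while larger jitter stresses robustness.

Ground-truth `FeatureScores` are defined as the score of the noiseless
planted pattern pushed through the same compose-and-score path: what a
perfect classifier would report for that geometry. This keeps truth
well-defined for emergent structure (e.g. a sparse diffuse slide really
does contain a confluent TIL-free region, and is scored as such).

Cohorts: event times are exponential with patient rate
baseline · exp(linear predictor) (Weibull optional, PH-parameterized),
censoring uniform over a 3000-day window, observed times rounded up to
whole days so ties occur as in day-resolution registries. The default
baseline rate (0.8/3000 per day) was chosen by the closed-form event
probability for exponential times under uniform censoring so that the
default cohort — half high-risk at a planted hazard ratio of 2 — yields
roughly 40% events. Category frequencies default to
population-based breast-cancer proportions (PAM50 LumA 0.51 / Basal 0.23 /
LumB 0.18 / Her2 0.08; ER+ 0.77; stage I–IV 0.39/0.46/0.13/0.02).

`phenotype_spectrum_specs` builds a screening-style cohort: 10% cold, 50%
sparse diffuse (density up to 0.30), 15% hot diffuse (0.75–0.95 — brisk
infiltrates whose TIL-free area falls below the desert threshold), 10%
forests, 10% deserts, 5% peritumoral rings. This spread exercises every
strength grade and both desert states, which is what makes the
strength-vs-infiltration correlation and the desert anticorrelation
measurable.

The rater simulator reports the truth with probability 1 − ε, else a
uniformly drawn adjacent category. For a binary feature ε = 0.5 makes the
report a fair coin and drives κ to chance level; ε = 1 would flip
deterministically and produce unanimous (perfectly agreeing, perfectly
wrong) panels — noise and disagreement are not the same thing.

All generators are pure functions of their spec; identical specs produce
bitwise-identical output.

## What passing tests do and do not show

The synthetic fixtures have sharp planted geometry, probability noise that
respects the binarization margin, exponential event times, and exact
labels. Passing the suite demonstrates that the scoring rules implement
their stated definitions, that the statistics match independent oracles,
and that planted effects of realistic size are recovered at desk scale
(n = 400, ~40% events; 200 seeds per phenotype; 300-slide spectrum
cohorts; 1000-replicate null calibration). It does not demonstrate
robustness to real CNN failure modes (tissue folds, stain variation,
correlated false positives), to non-proportional hazards, or to the
visual judgment differences of human scorers.

## Numerical choices

- Binarization uses ≥ (0.5 is positive); TIL-class uses strict > (ties
  Low); κ screening uses ≥ (the cutoff is retained).
- Heatmap CSV round-trips at `%.17g`; PNG probabilities are linear
  value/max-intensity with no gamma, so 8/16-bit round trips are exact.
- The strength grade is `sum(fraction > cutoff)` — a monotone step
  function, verified by sweep tests.
- Cox non-convergence raises; suspected complete separation is flagged in
  `CoxFit.warnings` rather than silently dropped.
- Seeds: every generator takes an explicit integer seed;
  `numpy.random.default_rng` throughout.
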