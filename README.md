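# tilscape

Spatial ecology of tumor-infiltrating lymphocytes (TILs) from
patch-classifier heatmaps.

Digital-pathology pipelines commonly run two convolutional patch
classifiers over an H&E whole-slide image: a tumor detector (87.5 µm
patches) and a lymphocyte detector (50 µm patches), each emitting a grid of
per-patch probabilities. `tilscape` is the analysis layer downstream of
those models, for pathologists and computational-pathology researchers who
want reproducible, scriptable TIL metrics:

- **Tumor-TIL maps** — binarize both heatmaps at probability ≥ 0.5, align
  them on their common 12.5 µm lattice (the GCD of the two patch pitches),
  and label every cell background / tumor / lymphocyte / co-positive.
- **Percent infiltration** — the slide-level TIL burden,
  `100 · #(tumor ∧ lymphocyte patches) / #(tumor patches)`, with cohort
  High/Low TIL classes split around the cohort mean (or median).
- **Spatial feature scores** — algorithmic versions of five
  ecology-inspired features: intratumoral strength (0–3), immune-cold
  *deserts* (1 when confluent TIL-free tumor regions cover ≥ 25% of tumor
  area), TIL *forests* (1 when confluent intratumoral TIL groups span
  ≥ 10% of tumor area), peritumoral strength (0–3, graded in a band around
  the invasive boundary), and distal tertiary lymphoid aggregates (1 when
  multifocal).
- **High-risk stratification** — each graded score maps to a binary
  high-risk indicator (strength 0–1, deserts present, forests absent,
  peritumoral 0–1); patients with **two or more** indicators form the
  high-risk group.
- **Rater consensus** — median-of-observers consensus scores and Fleiss'
  κ screening: features with κ < 0.5 are dropped from risk scoring (this
  is how aggregates leave the default indicator set).
- **Survival layer** — progression-free interval (PFI) analysis:
  Kaplan–Meier curves, log-rank tests, Cox proportional-hazards models
  with SD-scaled infiltration, Harrell's concordance index, and the
  TIL-sensitive cohort filter (ER-negative and/or PAM50 LumB/Her2).
- **Synthetic generator** — paired heatmaps with planted phenotypes
  (cold, diffuse, forest, desert, peritumoral ring, distal aggregates,
  mixed) and cohorts with planted hazard ratios, so every stage is
  testable without slide data.

## Worked example

```python
from tilscape import (PhenotypeSpec, plant_phenotype, binarize,
                      resample_to_common_lattice, compose_map,
                      percent_infiltration, score_all, high_risk_profile)

spec = PhenotypeSpec(phenotype="diffuse", diffuse_density=0.25, seed=7,
                     slide_id="demo-slide")
tumor_hm, lymph_hm, truth = plant_phenotype(spec)
pair = resample_to_common_lattice(binarize(tumor_hm), binarize(lymph_hm))
cmap = compose_map(pair)
print(percent_infiltration(cmap).percent_infiltration)
print(high_risk_profile(score_all(cmap)).group)
```

prints

```
24.53...
low-risk
```

The slide was planted with one in four tumor cells lymphocyte-positive, so
percent infiltration lands near 25%; at that density the intratumoral
strength is high and no desert can qualify, so fewer than two high-risk
indicators fire. The scripts in `examples/` walk through each capability
(map composition and rendering, spatial scoring, rater consensus with κ
screening, and the survival layer); for instance
`python examples/04_survival.py` simulates 400 patients with a planted
hazard ratio of 2.0 for the 2+ high-risk-feature group and recovers

```
Cox HR for 2+ high-risk features: 1.82 (95% CI 1.30-2.55), p=5.26e-04, concordance=0.57
```

A thin CLI mirrors the library for batch work:
`tilscape ingest|compose|score|consensus|survive|simulate --help`.

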