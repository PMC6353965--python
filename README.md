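# sdmrisk

Ensemble species distribution modelling and climate-change threat
assessment for narrow-ranged (endemic) species.

`sdmrisk` takes point occurrence records and gridded environmental
predictors and produces, per species: an ensemble habitat-suitability map,
projections onto future climate surfaces from several general circulation
models (GCMs), the projected percent change in potential range under two
dispersal assumptions, and an IUCN Red List criterion A3(c) threat
category. Community-level outputs are species-richness surfaces and
per-pixel temporal turnover. A virtual-species simulator generates every
input with known ground truth, so the entire workflow can be exercised —
and its accuracy measured — without any external data. It is aimed at
conservation biogeographers and macroecologists who want a reproducible,
fully scripted version of this standard assessment workflow.

## The model

For each species, presences `y=1` are contrasted against background
points `y=0` sampled inside a calibration region (the minimum convex
polygon of the occurrences, buffered by the mean pairwise great-circle
distance between them). Four member algorithms — a MaxEnt-like
L1-regularized logistic model on quadratic features, random forest,
gradient-boosted trees, and a linear logistic GLM — each yield a
suitability score `s_m(x) ∈ [0,1]`. Members are evaluated by 4-fold
spatial-block cross-validation (blocks split at the median longitude and
latitude), scoring

- AUC — the probability that a random presence outscores a random
  background point, and
- TSS = max over thresholds of (sensitivity + specificity − 1).

The consensus prediction is the weighted average `s(x) = Σ w_m s_m(x)`
with `w_m ∝ max(TSS_m, 0)`. Predictors are pre-screened twice: stepwise
removal of variance inflation factors VIF = 1/(1−R²) > 10, then permutation
importance, retaining predictors contributing > 5% (and never more
predictors than occurrences). Projections onto future predictor stacks are
*clamped* to the training range of each predictor, computed per GCM, and
aggregated as the cell-wise median. Ranges are binarized at the
max-TSS threshold from pooled cross-validation predictions; percent range
change `100·(future−current)/current` is mapped to categories
EX (100% loss), CR (>80%), EN (>50%), VU (>30%), LC otherwise, under
Unlimited Dispersal (future range as projected) and No Dispersal (future
range ∩ current range).

## Worked example

Simulate a small dataset (3 virtual species, 40×40 grid at 2.5 arc-min,
2 pseudo-GCMs) and run the full assessment:

```sh
sdmrisk simulate --outdir demo --n-species 3 --grid-size 40 \
    --n-presences 70 --n-gcms 2 --seed 5
sdmrisk run --config demo/run.yaml --outdir demo_run
```

`demo_run/threat_records.csv` then contains one row per species × horizon
× dispersal scenario:

```text
species_id  horizon scenario  current_cells  future_cells  change_pct category
     sp_00     2050       UD            277           119       -57.0       EN
     sp_00     2050       ND            277            67       -75.8       EN
     sp_00     2070       UD            277            49       -82.3       CR
     sp_00     2070       ND            277            12       -95.7       CR
     sp_01     2070       ND            263             0      -100.0       EX
     ...
```

Reading the first row: sp_00's binarized current range covers 277 grid
cells; by 2050, under unlimited dispersal, the GCM-median projection keeps
119 of the landscape's cells suitable — a 57% range loss, classified
Endangered (loss > 50%). Under no dispersal only cells inside the current
range count (67), so the loss is worse (75.8%); sp_01 loses its entire
range by 2070 under no dispersal and is classified Extinct. The manifest
records per-species fit quality, e.g. for sp_00: 39 records after
cleaning/thinning, a 71 km MCP buffer, spatial-CV AUC 0.91, TSS 0.81,
binarization threshold 0.26. `loss_band_counts.csv`, `richness_*.asc` and
`turnover_*.asc` summarize the cohort and the community surfaces, and
`manifest.json` lists every artifact with its SHA-256, so a rerun with the
same config and seed is verifiably bit-identical.

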