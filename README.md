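# deerlcu

Land Cover Utility (LCU) scoring for white-tailed deer habitat, plus the
multilevel Bayesian validation model, runnable end-to-end on synthetic
inputs.

The pipeline turns a categorical land-cover raster into a per-unit habitat
metric and checks that metric against (simulated) deer density data:

1. **Remap** land-cover classes into two habitat groups — *shelter/food*
   (forests, wetlands) and *food* (crops, pasture, grassland, shrub).
2. **Patches** — label 8-connected same-group patches, drop those smaller
   than 0.02 km², but keep same-group cells within 500 m of a surviving
   patch (deer tolerate mild fragmentation).
3. **Score** each qualifying cell by its distance to the nearest
   qualifying patch of the *opposite* group, using fixed distance bands
   (deer prefer habitat edges; remote forest cores still score 0.6, food
   beyond 500 m of shelter scores 0).
4. **Aggregate** scores into an LCU value per spatial unit and land-cover
   year: score sum ÷ unit area (km²), at three nested levels
   (section/TRS ≈ 2.6 km², township ≈ 94 km², county).
5. **Validate** with a two-level Bayesian Gamma log-link regression of
   minimum deer density on LCU plus hunting covariates (no-hunt area,
   public hunting sites, prior-year density), with unit and year random
   intercepts, 2-SD covariate standardization, an 80/20 train/test split,
   Rhat/ESS convergence gates, Bayesian R², and held-out prediction error.
6. **Simulate** everything needed to exercise 1–5 offline: clustered
   landscapes, nested unit tilings, and Gamma-GLMM density panels with
   known parameters for recovery studies.

Inference uses a self-contained adaptive HMC sampler (`deerlcu.mcmc`)
over a non-centered parameterization; `arviz` supplies Rhat/ESS
diagnostics. A fast penalized-likelihood MAP fit (`fit_gamma_map`) is
available for smoke checks.

## CLI

```bash
lcu simulate landscape --nrows 400 --ncols 400 --seed 1 --out land.asc
lcu simulate units --raster land.asc --out units.geojson
lcu remap --raster land.asc --year 2021 --out groups.asc
lcu patches --groups groups.asc --out qualifying.asc
lcu score --groups groups.asc --out scores.asc
lcu aggregate --scores scores.asc --units units.geojson --year 2021 --out lcu.csv
lcu simulate panel --n-units 500 --n-years 9 --seed 1 --out panel.csv
lcu validate --data panel.csv --seed 1 --out result.json
```

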