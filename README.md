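# georisk

Geospatial disease-susceptibility mapping as a reusable, fully seeded
pipeline:

1. **Synthetic spatial database** — Gaussian-random-field criterion
   surfaces (circulant-embedding FFT, spherical covariance with a nugget
   fraction), sparse monitoring-station samples, and case points drawn from
   an inhomogeneous point process whose log-intensity is a known linear
   combination of driver criteria.
2. **Geostatistics** — omnidirectional empirical semivariograms (Matheron
   estimator), spherical/exponential/gaussian model fitting (Cressie-
   weighted least squares), the spatial-dependence index
   `SD = 100 · nugget / (nugget + partial sill)` with strong/moderate/weak
   classes, and ordinary kriging of station samples to rasters.
3. **Spatial autocorrelation** — global and local Moran's I (analytic
   randomization or permutation inference, H-H/H-L/L-H/L-L cluster labels)
   and Getis-Ord global G / local Gi* hot- and cold-spot z-scores on
   grid-aggregated case counts.
4. **Frequency-ratio weighting** — natural-breaks (exact Fisher-Jenks),
   quantile or manual class schemes; per-class FR = F_i / P_i computed from
   training presences only; FR-weight reclassification of each criterion.
5. **Susceptibility model** — balanced presence/pseudo-absence samples
   (seeded, with a minimum distance to presences), random-forest
   classification on the FR-weight features, a continuous probability
   raster, and a 5-class natural-breaks risk map.
6. **Validation** — ROC/AUC (trapezoidal, equal to the rank statistic),
   RMSE/MAE, and leave-one-factor-out sensitivity via the relative-decrease
   index `RD = 100 · (AUC_all − AUC_i) / AUC_all` scored on out-of-bag
   training predictions.

Rasters are read and written as **ESRI ASCII grids** (`.asc`) so every
artifact of a run is plain text; points travel as CSV or GeoJSON, reports
as JSON/CSV.

## CLI

```bash
# full pipeline on the default synthetic scenario (13 criteria, 3 drivers,
# 872 cases, 70/30 split)
georisk run-all --seed 1 --out my_run

# with a config file
georisk run-all --config config.yaml
# single stages (re-run the seeded pipeline and list that stage's outputs)
georisk variogram --seed 1 --out my_run
georisk sensitivity --seed 1 --out my_run
```

A config file is a YAML mapping of `PipelineConfig` fields, e.g.

```yaml
seed: 7
n_criteria: 13
n_cases: 872
driver_indices: [0, 1, 2]
driver_coefficients: [1.5, 1.2, 1.0]
train_fraction: 0.7
n_trees: 100
out_dir: run7
```

A run directory contains the criterion and kriged rasters, station/case
tables, `variograms.json` (nugget / partial sill / range / SD per
criterion), `autocorrelation.json` (index value, z, p, distribution type),
local-Moran and Gi* label rasters, `fr_tables.csv`, `importances.csv`,
probability and 5-class susceptibility rasters, `validation.json`
(AUC/RMSE/MAE/TP/FP for train and test), `sensitivity.csv` (AUC_i and RD
per excluded criterion), and a `manifest.json` keyed by the config hash.

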