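# phenorhythm

Structural-trait extraction and rhythm statistics for terrestrial laser
scanning (TLS) time series of field crops, with a synthetic maize
point-cloud generator that provides closed-form ground truth for every
stage of the pipeline.

The package covers the full workflow:

1. **`phenorhythm.synth`** — parametric maize plants (stem cylinder plus
   ruled-surface leaves with prescribed length, width, inclination, azimuth
   and droop), logistic seasonal growth, sinusoidal day-scale movement,
   Poisson surface sampling with Gaussian sensor noise, and diurnal
   PAR / temperature / relative-humidity series at half-hour cadence.
2. **`phenorhythm.io` / `phenorhythm.preprocess`** — ASCII XYZ(L), binary
   PLY and LAS (read-only) point clouds; clipping, statistical outlier
   removal, DTM-based height normalization and planting-grid plant
   clustering.
3. **`phenorhythm.plant_traits`** — nine plant-level traits: maximum /
   mean / 99 %-quantile height, crown size, plant azimuth, projected leaf
   area (PLA), convex-hull volume, projected area index (PAI) and a 3D
   profile index (3DPI).
4. **`phenorhythm.leaf_traits`** — nine leaf-level traits via midrib
   slicing: length, maximum / mean width, leaf height, area, projected
   leaf length (PLL), PLA, inclination and azimuth.
5. **`phenorhythm.rhythm`** — Tukey HSD with a compact letter display for
   seasonal comparisons, hourly-growth-rate de-trending of circadian
   series, natural cubic-spline interpolation of environmental records,
   and Pearson trait-environment correlation with significance tiers.
6. **`phenorhythm.pipeline` / `phenorhythm.cli`** — reproducible
   end-to-end runs with a YAML config, manifest and per-file checksums.

Coordinate convention: z up, +y = geographic north, +x = east, meters.
Azimuths are clockwise from north; plant azimuth is undirected (mod 180°),
leaf azimuth is directed base→tip (mod 360°).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (geometric
oracles, 50-leaf parameter recovery, Tukey type-I/power calibration,
spline/de-trending identities, and end-to-end seasonal/circadian runs);
the remaining files are per-module unit and property tests.

## CLI

```bash
# full simulated run (seasonal mode): traits + Tukey letters
phenorhythm run --outdir out --mode seasonal --n-plants 10 --seed 1

# circadian mode: de-trended series + environment correlations
phenorhythm run --outdir out_c --mode circadian_standard --seed 1

# individual stages
phenorhythm simulate --outdir sim --n-plants 3          # writes clouds/
phenorhythm preprocess sim/clouds/*.xyz --outdir pre
phenorhythm traits pre/*.xyz --out traits
phenorhythm seasonal traits/plant_traits.csv --out letters.csv
phenorhythm circadian traits.csv env.csv
```

All tunables (grid cell sizes, voxel size, slice count, SOR parameters,
alpha, de-trend anchors, seed) can be given in a YAML config passed via
`--config`; every output CSV carries the config hash and seed, and
`manifest.json` records checksums so reruns can be verified bit-identical.

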