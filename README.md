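# muscletrace

Quantitative analyses for esophagus striated muscle (ESM) progenitor
studies. ESM progenitors are cardiopharyngeal-mesoderm-derived cells that
colonize the esophagus by anterior–posterior migration while delaying
myogenic differentiation; characterizing them combines single-cell qPCR,
time-lapse explant imaging, single-molecule in situ hybridization
(RNAscope), and section-image quantification. `muscletrace` packages those
four analyses as a tested, reusable pipeline, plus seeded synthetic-data
generators that emulate each input type so everything runs with no
downloads.

## What it computes

- **Single-cell qPCR** (`muscletrace.qpcr`): limit of detection
  `LOD = ⌈mean(per-gene max Ct)⌉`; relative expression
  `Log2ex = max(0, LOD − Ct)`; per-cell housekeeping normalization with a
  recorded global offset; cell filtering (no exclusion markers, ≥4/5
  controls, ≥2 genes of interest detected); pairwise-complete mid-rank
  Spearman correlograms (rho, two-sided p, per-pair n); complete-linkage
  heatmap ordering; bulk `2^ΔCt` expression and primer efficiency
  `E = 10^(−1/slope)`. Exposed both as functions and as scikit-learn style
  estimators (`ExpressionConverter`, `HousekeepingNormalizer`,
  `CellQualityFilter`, `SpearmanCorrelogram`).
- **Migration tracks** (`muscletrace.tracks`): per-track total distance,
  velocity, displacement, efficiency (straightness index) and net velocity;
  two-sided Mann-Whitney group comparisons (exact for small untied samples).
- **RNAscope scoring** (`muscletrace.rnascope`): ordinal dot-count scores
  (0 dots → 0, 1–3 → 1, 4–9 → 2, ≥10 → 3, big cluster → 4), marker × score
  cross-tabulation with the derived percentages, and per-compartment
  reporter (chimerism) percentages.
- **Image quantification** (`muscletrace.image_quant`): ImageJ-style
  "Default"/IsoData and Huang automatic histogram thresholds, masked area
  measurements and area ratios.
- **Synthetic data** (`muscletrace.synthetic`): seeded generators for
  block-correlated LOD-censored Ct matrices, biased persistent random-walk
  tracks, negative-binomial dot counts, and blob images with ground truth.

## Worked example

```python
import muscletrace as mt

# a study-default synthetic run: 66 cells, 14-gene panel, LOD censoring
ct, truth = mt.simulate_ct_matrix(seed=1)
lod = mt.compute_lod(ct)
expr = mt.ct_to_expression(ct, lod)
report = mt.filter_cells(expr)
norm = mt.normalize_to_controls(expr.subset_cells(report.retained_cells))
corr = mt.spearman_correlogram(norm, genes=["Isl1", "Met", "Pax7", "Myf5"])

print("LOD =", lod.value, "cycles")
print("retained", report.n_retained, "of", report.n_input, "cells")
print(corr.rho.round(2))
```

prints

```
LOD = 21 cycles
retained 23 of 66 cells
      Isl1   Met  Pax7  Myf5
gene
Isl1  1.00  0.69  0.63  0.61
Met   0.69  1.00  0.62  0.58
Pax7  0.63  0.62  1.00  0.81
Myf5  0.61  0.58  0.81  1.00
```

The LOD rule lands on 21 cycles; of 66 simulated cells, the contaminant and
low-quality fractions are removed leaving 23; and the planted co-expressed
progenitor block (Isl1, Met, Pax7, Myf5) comes out all-positive in the
correlogram, with the expected attenuation from detection censoring.

The same stages are scriptable from a shell:

```bash
muscletrace simulate qpcr --seed 5 --out sim/
muscletrace qpcr --ct sim/ct_matrix.csv --panel sim/panel.yaml --out out/
# -> LOD=21 cycles; retained 23/66 cells; offset=6.4913
muscletrace tracks --input tracks.csv --interval-min 15 --out out/
muscletrace rnascope --input dots.csv --out out/
muscletrace image --channel section.tif --method huang --out out.csv
muscletrace run --config run.yaml          # config-driven, writes manifest.json
```

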