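# Methods

`muscletrace` implements the quantitative analyses used to characterize
esophagus striated muscle (ESM) progenitors — cardiopharyngeal-mesoderm-derived
cells that colonize the esophagus by anterior–posterior migration under
MET/HGF signaling while holding off myogenic differentiation. Four largely
independent analyses are covered: single-cell qPCR co-expression, time-lapse
migration-track statistics, RNAscope dot-count scoring, and threshold-based
image area quantification. A synthetic-data module generates seeded inputs
with the statistical structure each analysis assumes, so the whole package
builds and tests without any external data.

## Single-cell qPCR pipeline

**Model.** A microfluidic (BioMark-style) qPCR run reports, per gene and
cell, the cycle threshold Ct; wells with no amplification carry a fail
sentinel (999 by default, "Undetermined" and blank cells are treated the same
way). The pipeline is:

1. **Limit of detection (LOD).** Per gene, take the maximum Ct over
   non-failed wells; the LOD is the ceiling of the mean of these maxima.
   Genes with only failed wells cannot contribute and raise an error (they
   can be excluded via `gene_subset`). On the synthetic study-default matrix
   this rule lands on 21 cycles.
2. **Relative expression.** `Log2ex = max(0, LOD − Ct)`; failed wells map to
   0. A well is *detected* iff Ct < LOD, and the detection mask travels with
   the matrix: downstream steps re-read undetected entries as 0 (clustering)
   or missing (correlation).
3. **Housekeeping normalization.** For each cell, the mean h_c of its
   normalizer-gene values (Actb, Rpl13a, Rps29, Hprt by default; zeros
   included) is subtracted, and a global offset — the mean of all h_c — is
   added back so values stay nonnegative on average. The shift is applied to
   every non-failed value of the cell, which makes the identity "each cell's
   normalizer mean equals the offset" hold exactly; the detection mask is
   unchanged. By default the offset is computed on the post-filter matrix
   (the alternative is one flag away); since filtering depends only on the
   detection mask, the two orderings retain the same cells.
4. **Cell filtering.** A cell is retained iff it detects no exclusion marker
   (Pax3, Lhx3 — neurogenic contamination; the set is configurable because
   assay panels vary), detects at least 4 of the 5 control genes, and at
   least 2 genes of interest. The report lists every failed criterion per
   cell, and filtering is idempotent.
5. **Spearman correlogram.** Undetected values become missing; each gene
   pair is correlated over its pairwise-complete cells using mid-rank
   Spearman rho, with a two-sided p from the t-approximation
   (df = n_pairs − 2). Pairs with fewer than `min_pairs` (default 3)
   complete observations, or a constant variable, are NaN — never a silent
   zero. The per-pair sample sizes are reported alongside rho and p.

**Heatmap ordering** uses agglomerative complete-linkage clustering on
Euclidean distances (undetected entries as 0), with a deterministic
tie-break: among equal-height merge candidates, the pair whose clusters
contain the lowest original leaf indices merges first. Heights agree with
scipy's complete linkage; the tie-break only fixes the order of exact ties.

**Bulk helpers.** Relative bulk expression is `2^(Ct_ref − Ct_target)`
against a reference transcript (TBP in the original assays), and primer
amplification efficiency from a dilution series is `E = 10^(−1/slope)` with
slope from the regression of Ct on log10(dilution); a perfect doubling assay
has slope ≈ −3.32 and E = 2.

**A note on normalization-induced correlation.** Subtracting a noisy
per-cell housekeeping mean adds a shared component (−h_c) to every gene in
the cell, which places a positive correlation floor under *all* gene pairs —
in the synthetic default conditions about +0.28 on pairs whose latent
correlation is zero. This is inherent to the published normalization, not an
implementation artifact; it is why the generator's null-structure test runs
on unnormalized expression, and why correlogram values should be read
relative to one another rather than against zero.

## Migration-track metrics

Tracks are ordered 2D positions (μm) per cell, one frame every 15 min by
default (the acquisition interval; a per-file override covers 12–15 min
protocols). Five statistics per track: total distance (summed step lengths),
velocity (total distance / total time), displacement (first-to-last
straight-line distance), efficiency (displacement / total distance — the
straightness index, 1 for straight motion and 0 for a closed loop), and net
velocity (displacement / total time). Total time is the *frame span* times
the interval, so skipped frames do not shorten the clock; steps are computed
between consecutive recorded points. Group comparisons use the two-sided
Mann-Whitney U test: exact null distribution when n₁·n₂ ≤ 400 with no ties,
otherwise the normal approximation with continuity and mid-rank tie
correction.

## RNAscope dot scoring

Per-cell transcript dots map to an ordinal score: 0 dots → 0, 1–3 → 1,
4–9 → 2, ≥10 → 3, and a "big cluster" (unresolvable dot mass, flagged by the
scorer, not computed) → the top score. The default scale is 0–4 with
clusters in their own top bin; a compact 0–3 scale folds clusters into 3.
A count of exactly 10 scores 3 (the verbal bin edges skip it; grouping it
with the high scores matches how high expression is summarized). Scores are
cross-tabulated against differentiation-marker status (e.g. Myod/Myog
nuclear staining), reporting % marker-positive overall, % low score (0–1)
within positives and % high score (3–4) within negatives, rounded to
integers by default; a percentage over an empty class is flagged undefined
rather than reported as 0. The same counting machinery serves per-compartment
reporter-contribution percentages for chimera experiments.

## Image thresholds and areas

Histograms use one bin per integer gray level at the image bit depth. Two
automatic thresholds are implemented to match the Fiji menu entries used for
section quantification: the legacy "Default" iterative intermeans (which
zeroes the extreme bins first so saturated/erased pixels cannot drag the
class means, and falls back to the midpoint level when nothing else remains),
the classic IsoData fixed point `T = round((mean≤T + mean>T)/2)`, and the
Huang–Wang fuzzy-entropy minimizer (membership `1/(1 + |g − m(g,T)|/C)` with
C the occupied intensity range; Shannon entropy of memberships summed over
the histogram; ties broken toward the lower threshold). Foreground is
*strictly above* the threshold (ImageJ measure-over-threshold behavior;
a flag switches to ≥). Areas are pixel counts inside the ROI, converted to
μm² when a pixel size is supplied, and ratios of thresholded areas (e.g.
transcript signal per smooth-muscle area) divide the foreground counts.

## Synthetic data: what it emulates, and what it does not

- **Ct matrices.** Latent log2 expression is multivariate normal with a
  planted block structure: the upstream progenitor genes (Isl1, Met, Pax7,
  Myf5) share pairwise latent correlation 0.75 and are detected in nearly
  every cell; the downstream MRFs (Myod, Myog, Mrf4; pairwise 0.5) sit
  mostly below detection; the five controls are high-mean; cross-block
  latent correlation is exactly zero. Ct = LOD_true − latent with
  LOD_true = 21; a well with latent ≤ 0 is below the instrument's detection
  limit and is recorded as a failed well, so dropout is pure LOD censoring
  and the LOD rule recovers 21 from the simulated maxima. Means and sds
  (controls 6 ± 2.5, upstream 5 ± 2.5, downstream −2 ± 2.5 on the Log2ex
  scale) put overall interest-gene censoring near 35%, consistent with MRFs
  being expressed in a subset of cells. Of 66 cells, 30% are neurogenic
  contaminants (exclusion markers pushed above detection) and 35% are
  low-quality (three control genes forced below detection), leaving ~23
  clean cells — the study's input/output sizes. The block correlation was
  set by a power argument made once: at n ≈ 23, sample noise on rho is
  ~0.21, so 0.75 keeps all six block pairs positive in ≥90% of replicates.
- **Tracks.** Biased persistent random walks: heading perturbed by a
  wrapped-normal step (spread π(1 − persistence), persistence 0.6), step =
  drift·dt (posterior +x; 0.3 μm/min control vs 0.1 μm/min inhibitor) +
  motility 0.15 μm/min along the heading + 1 μm isotropic jitter; 57 frames
  of 15 min (14 h), 30 tracks per condition.
- **Dots.** Negative-binomial counts, mean 12 for marker-negative
  (undifferentiated) vs 2 for marker-positive cells, dispersion (size) 2 —
  moderate overdispersion typical of single-molecule counts; big-cluster
  probability 0.20 vs 0.02; 368 cells with P(marker+) = 0.34.
- **Images.** Uniform disks (intensity 180) over background 30 with
  Gaussian noise sd 10 on a 256×256 8-bit frame, plus the exact foreground
  mask.

Every generator is a pure function of parameters and seed. What passing
tests on these data do **not** show: the generators have no spatial gene
structure, no cell-cycle or batch effects, no PCR efficiency variation
between genes, no track interactions or drift heterogeneity, and no
non-uniform illumination or texture in images. Results on real data depend
on those factors; the tests validate the arithmetic and the statistical
machinery, not biological effect sizes.

## Numerical choices and degenerate inputs

- Fail sentinel ≥ 999 (configurable); sentinel, "Undetermined" and blank
  cells are equivalent on read.
- "Expressed"/"detected" means strictly Log2ex > 0 (Ct < LOD).
- Correlations: `min_pairs = 3`; undefined entries are NaN everywhere
  (never 0); exact-tie mid-ranks via the standard mid-rank convention.
- Clustering tie-break: lexicographic on contained leaf indices; a
  single-row or single-column axis yields a trivial order with no linkage.
- Mann-Whitney exact/asymptotic switch at n₁·n₂ = 400 or any tie.
- Threshold ties (Huang): lowest optimal threshold. Intermeans on a
  histogram whose mass survives only at one level after extreme-bin zeroing
  returns the midpoint gray level ("Default") — a genuinely single-valued
  histogram is an error for all methods.
- Simulated Ct values are clipped at 1 cycle (a latent far above the LOD
  would otherwise produce a nonpositive Ct).

## Problem sizes used by the shipped checks

The replicate-based checks (block recovery, drift detection, brute-force
threshold agreement) use 200 seeded replicates at the study-default sizes
(66 cells, 30 tracks/group, 256-bin histograms); oracle-equivalence checks
use 100 random 8-gene × 30-cell matrices, 100 random 6-point linkage
problems, and 200 random histograms. These sizes make every distributional
claim measurable at the stated rates while keeping a full run in the order
of seconds to a minute on one CPU.

## Known limitations

- The two deposited per-cell source tables of the original study have no
  public accession; the checks that reproduce its exact headline numbers
  (LOD 21 on the real matrix, 66→23 cells, 368-cell crosstab percentages)
  run only when those files are placed under `data/source/` and are skipped
  otherwise. The same quantities are recomputed on the synthetic
  study-default conditions instead.
- Pairwise-complete correlations involving sparsely detected genes rest on
  few cells and are high-variance; together with the normalization-induced
  correlation floor (above), per-replicate orderings between weak
  correlations are unstable, and only the strongly correlated block is
  reliably recovered per replicate.
- ROI handling accepts masks (or rasterized polygons via the CLI); no
  registration, stitching, or spot detection is provided — dot counts and
  cluster flags are inputs.
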