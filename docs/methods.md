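# Methods

## Overview

`somportrait` implements SOM expression portrayal: a self-organizing map is
trained on preprocessed gene expression profiles so that each lattice unit
("metagene") carries a prototype profile with one value per sample, genes map
to their best-matching unit (BMU), and neighboring units end up correlated.
One sample's metagene values, arranged on the lattice, are its *portrait*;
coherent overexpression regions ("spots") in group-mean portraits are modules
of co-regulated genes. Downstream statistics (spot networks, sample trees,
gene-set tests) all operate on the metagene representation.

## Preprocessing

Input is a genes × samples table of non-negative, library-size-normalized
abundances (CPM). The pipeline is `log10(x + pseudocount)` → quantile
normalization → gene-wise centering, enforced through a scale tag so stages
cannot run out of order.

- **Pseudocount** (default 1.0): maps zero CPM to zero log-expression, the
  most common convention.
- **Quantile normalization**: every column is mapped onto the sorted-mean
  reference distribution; tied values receive the average of their target
  quantile values. With ties the per-column sorted vectors can differ
  slightly (tie blocks are averaged per column); the transform remains
  idempotent.
- **Centering** subtracts each gene's mean, so profiles express deviation
  from the gene's average and between-sample differences within a gene are
  untouched.
- **Gene-ID conversion** re-keys the matrix through a partial old → new map
  (from a GFF3 attribute pair or a two-column TSV); unmapped genes are
  dropped and reported, and kept + dropped = input always holds. Map
  collisions (two old IDs → one new ID) are an error, not a silent merge.

## SOM training

Batch Kohonen training on a quadratic lattice (default 40 × 40 = 1,600
units, 50 epochs):

1. assign every gene to its BMU (minimal Euclidean distance; ties go to the
   lowest unit index);
2. replace every prototype with the Gaussian-neighborhood-weighted mean of
   the per-unit gene sums, kernel `exp(−d²/2σ²)` on squared lattice distance,
   with σ decaying exponentially from `max(rows, cols)/2` to 0.5 across
   epochs.

Initialization is `pca-linear`: prototypes laid on the plane of the first
two principal directions (±2 component SD), with SVD signs fixed, so batch
training is fully deterministic — the seed only matters for the optional
`random` init and the online training mode. The final BMU table is
recomputed against the final codebook, so BMU optimality holds exactly.
Quantization error is tracked per epoch and a warning is emitted if it rises
during the final 10% of epochs. Empty units keep their converged prototypes.
An online (sequential) mode exists for comparison; it is markedly slower and
intended for small inputs only.

## Spots and the spot network

Per portrait, units at or above the **98th percentile** of the portrait's
values are marked; 8-connected components with **≥ 4 units** become spots,
labeled in decreasing peak order. A degenerate constant portrait has every
unit at the threshold and yields one lattice-spanning spot. For the catalog,
spots are segmented from each group-mean portrait (typically one group per
condition) and spots sharing ≥ 1 unit across groups are merged (union of
units), so the catalog is non-redundant and unit-disjoint; genes are
assigned by BMU membership, and genes outside every spot are reported as
unassigned.

Spot expression profiles (mean prototype over the spot's units, per sample)
feed a weighted-topological-overlap network: adjacency is |Pearson| between
spot profiles (unsigned; the signed matrix is exported alongside), and

    ω_ij = (Σ_u a_iu a_uj − a_ii a_ij − a_ij a_jj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with k_i = Σ_{u≠i} a_iu. ω is symmetric, unit-diagonal, in [0, 1], and for
exactly two spots reduces to ω₁₂ = a₁₂. Zero-variance profiles get zero
correlation with a warning.

## Sample tree and clade report

Sample distances default to 1 − Pearson between metagene profiles (codebook
columns) — the same space the portraits visualize; Euclidean distance and
gene-space profiles are options. The tree is classical neighbor joining with
a deterministic tie-break (lexicographically smallest label pair, internal
nodes represented by their smallest leaf label); negative branch lengths are
clamped to zero with a warning; output is an unrooted tree (newick).

For reporting, the tree is midpoint-rooted and each condition's **major
clade** is the clade maximizing the Jaccard overlap between its leaves and
the condition's samples (ties → smaller clade). A condition "has" a major
clade when that Jaccard exceeds 0.5; samples outside their condition's major
clade are *out-grouped*. The Jaccard criterion was chosen over a purity
threshold because a mixed clade that absorbs a few foreign transition
samples should not be able to claim them: maximizing Jaccard keeps the major
clade tight and flags the interlopers. Counts of maximal fully-pure clades
per condition are reported alongside.

## Gene-set statistics

- **Overrepresentation**: exact hypergeometric upper tail P[X ≥ k] of a
  set's overlap with a spot's genes, computed against the analysis universe.
  The universe defaults to all genes that entered SOM training (not the
  genome) because spots can only contain analyzed genes; it is overridable.
  Benjamini–Hochberg adjustment is applied across the full spot × set table.
- **Per-sample set Z-score**: `z_s = (mean_set,s − mean_all,s) /
  (sd_all,s / √m)` on the centered matrix, with m the set size after
  intersection with the matrix. This is a one-sample location score against
  the sample-wide expression distribution; other GSZ variants exist, and the
  implementation is deliberately a small, replaceable function.
- **Top genes**: spot members ranked by mean centered expression over a
  sample group, ties broken by gene ID.
- GMT files are the exchange format for sets; set-per-spot member counts are
  exported for gene-family censuses.

## Synthetic data generator

The generator emulates a 5-cultivar × 4-temperature × 3-replicate leaf
RNA-seq study with one dropped replicate (59 samples). On the log10 scale,
gene g in sample s is

    baseline_g + Σ_m effect_m · w(condition_m, s) + cultivar_offset_{g,c(s)}
               + λ_g · z_{m(g),s} + ε_{g,s}

back-transformed as `10^value` (strictly positive, CPM-like). Defaults, all
chosen once as study-like conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes | 5,000 | desk-scale stand-in for ~18k measured genes |
| baseline | log10-normal(1.5, 0.8) | typical CPM magnitudes without read-count modeling |
| noise_sd | 0.25 log10 units | moderate replicate scatter |
| cultivar_sd | 0.05 | cultivar effects small, so condition dominates clustering |
| modules | one per condition, 130 genes, effect 1.0 | footprint ≈ the 2% segmentation quantile area of the 40×40 map, so a module and its spot are commensurate |
| within-module correlation | 0.35 | induced by a shared per-module, per-sample latent factor splitting the noise variance; moderate, since the condition effect itself already co-locates module genes |
| planted set | 22 genes inside the acclim module | a small pathway-sized set for enrichment ranking |
| decoy sets | 30 × 22 random genes | negative controls for the ranking |
| outliers | 2 accfreeze samples mixed 0.7 → acclim, 1 freeze sample mixed 0.7 → warm | transition states: expected log profile is the convex mixture of two condition signatures |

With mixing weight 0 or 1 an outlier's expected profile equals a pure
condition profile exactly. A single master seed drives four independent
sub-streams (baseline, cultivar, module factors, noise), so identical
configurations are bit-identical.

**What the generator does not emulate**: count noise (no negative-binomial
layer, no library-size variation), correlated backgrounds between conditions,
graded similarity between neighboring temperatures, multiple modules per
condition, or gene-length effects. Passing recovery tests therefore show the
pipeline recovers planted block structure under log-normal noise — they do
not certify performance on real count data, where module boundaries are
softer and spot counts are larger.

A note on transition outliers: at mixing weight 0.7 an outlier's signature
contrast is comparable to the shared module-factor noise, so its tree
placement genuinely varies with the replicate-noise draw — much like the
real phenomenon, where only some replicates stand out. Recovery assertions
are therefore made at fixed seeds.

## Problem sizes and determinism

Default study-scale runs (5,000 genes × 59 samples, 40 × 40 map, 50 epochs)
complete in well under a minute; the test suite uses 600-gene / 16×16
configurations for most properties and one full-scale run for the structural
recovery checks. Batch training, pca-linear init, and fixed tie-breaks make
every pipeline artifact byte-reproducible for a given config + seed.

## Known limitations

- Exact reproduction of real-data spot counts/sizes requires the original
  expression table and the original tool's undocumented training settings;
  this package matches the workflow's structure, not bit-level output.
- The 98% / ≥4-unit / 8-connectivity segmentation convention is simple and
  auditable but has no adaptive thresholding; very large or very diffuse
  modules will be truncated or split.
- Only unmapped-ID removal is implemented as a preprocessing filter (with a
  report); expression-level filters are left to the caller.
- The NJ implementation is O(n³)–O(n⁴) in leaves with Python-level loops:
  fine for tens to a few hundred samples, not for thousands.
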