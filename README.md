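# somportrait

**Self-organizing-map expression portrayal for condition-series transcriptomes.**

`somportrait` turns a genes × samples abundance matrix (CPM or similar) into:

- **sample-specific expression portraits** — a Kohonen map distributes the
  genes over a quadratic lattice of *metagenes* (prototype profiles); each
  sample's metagene values, colored blue → green → maroon, form its portrait;
- **overexpression spot modules** — connected lattice regions above a
  quantile threshold of a group-mean portrait, merged across groups into one
  catalog; each spot carries the genes whose best-matching unit (BMU) lies
  inside it;
- **a spot correlation network** — pairwise weighted topological overlap
  (wTO) of spot expression profiles across samples;
- **a neighbor-joining sample tree** with a per-condition clade report that
  flags "out-grouped" samples (transition-state candidates);
- **gene-set statistics** — exact hypergeometric overrepresentation of GMT
  gene sets in each spot (BH-adjusted), per-sample gene-set Z-scores, and
  top-gene rankings.

The package targets multi-condition bulk RNA-seq designs such as a
5-cultivar × 4-temperature grapevine cold-stress experiment (warm 21 °C,
acclim 4 °C, accfreeze 4→−3 °C, freeze −3 °C; 59 leaf samples), and ships a
synthetic-data generator that reproduces that design with planted,
recoverable structure, so the whole pipeline is testable offline.

## Method in brief

Genes are preprocessed as `log10(CPM + 1)` → quantile normalization →
gene-wise centering. A batch SOM on a `rows × cols` lattice (default 40 × 40
= 1,600 metagenes) alternates BMU assignment (Euclidean) with a
Gaussian-neighborhood weighted prototype update, the radius decaying
exponentially from `max(rows, cols)/2` to 0.5 over 50 epochs; initialization
is deterministic on the first two principal directions. Spots are
8-connected components of lattice units at or above the 98th percentile of a
portrait with ≥ 4 units. Overrepresentation of a set of size *K* in a spot
of size *n* within a universe of *N* genes is the exact upper tail
P[X ≥ k], X ~ Hypergeom(N, K, n). The per-sample set Z-score is
`z = (mean_set − mean_all) / (sd_all / √m)` on the centered matrix. Sample
trees use 1 − Pearson on metagene profiles and classical neighbor joining.

## Worked example

Run the default synthetic study end to end (5,000 genes, 59 samples,
40 × 40 map; one planted 130-gene module per temperature condition, a
22-gene "thiamine-like" set inside the acclim module, and three planted
transition-state outlier samples):

```bash
somportrait run --outdir demo --seed 17
```

prints

```
run complete: 59 samples, 5000 genes, 4 spots, 4 major clades -> demo/run_report.yaml
```

and writes TSV/PNG/newick artifacts. The spot catalog (`demo/spot_catalog.tsv`)
recovers one module per condition:

```
label  source     n_units  n_genes  peak_value  peak_row  peak_col
A      warm       32       130      0.761       1         38
B      acclim     32       129      0.747       39        39
C      accfreeze  32       133      0.682       0         0
D      freeze     32       126      0.722       8         0
```

Each condition's planted module surfaces as one 32-unit spot in its own
lattice corner, holding essentially the module's genes. The clade report
(`demo/clade_report.tsv`) shows the neighbor-joining tree splitting into
four temperature clades, and `run_report.yaml` lists the out-grouped
samples — exactly the three planted transition outliers:

```
outgrouped_samples: [Riesl_accfreeze_r1, Riesl_accfreeze_r3, Tocai_freeze_r1]
```

The top enrichment hit for the acclim spot (`demo/enrichment_top.tsv`) is
the planted set, far ahead of the 30 decoy sets:

```
spot  set            k   n    K   N     p_value      adj_p
B     thiamine_like  22  129  22  5000  1.78e-36     2.21e-34
```

The same stages are available programmatically
(`somportrait.generate_expression`, `normalize_for_som`, `train`,
`group_spot_summary`, `neighbor_joining`, `enrich_all`, …) and as individual
CLI subcommands (`simulate`, `preprocess`, `train`, `spots`, `tree`,
`enrich`, `validate`).

To analyze real data instead, point the run config at an expression table
and sample sheet (`expression_path`, `sample_sheet_path`), optionally with a
GFF3- or TSV-based gene-ID map; see `examples/run_config.yaml` for the full
set of knobs.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and its
defaults, numerical conventions, and known limitations.
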