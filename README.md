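# coregdom

Genome-order co-regulation analysis for stimulus-response epigenomics.

When a signalling pathway (the motivating system is TGFβ stimulation of
mammary epithelial cells) remodels chromatin, regulated enhancers and genes
are not scattered independently along the genome: co-regulated genes
cluster into contiguous runs, enhancers influence several neighboring genes
in order, and the clustering interacts with 3D chromatin structure (TADs).
`coregdom` implements the full analysis stack for quantifying this, for
computational biologists working from tabular derivatives of ATAC-seq,
ChIP-seq, RNA-seq and Hi-C experiments — plus a synthetic-genome generator
that plants known structure so every stage can be validated end to end.

## What it computes

* **Response categories.** Expressed genes are classified from three log2
  fold-change comparisons (2 h vs vehicle, 12 h vs vehicle, 12 h vs 2 h)
  into early-up/down, late-up/down, transient-up/down or independent, with
  p < 0.05 gating; e.g. early-up: log2FC(2h) > 1 and not log2FC(12v2) < −1.
  Robust genes additionally satisfy |log2FC| > 1 with adjusted p < 0.05.
  Enhancers are classified by the same rules applied to H3K27ac
  differential binding (adding mean log2CPM > 0), binned by linear
  accessibility fold change (FC<1.5, 1.5≤FC<2, 2≤FC<4, FC≥4), and assigned
  chromatin states (latent / primed / active) from percentile-thresholded
  H3K27ac and H3K4me1 signal.
* **Neighborhood statistics.** Expressed genes are numbered 1..n per
  chromosome by TSS; Eg±n denotes the n-th expressed gene on either side of
  an enhancer summit in chromosome order. Per-position log2FC distributions
  are compared with circular-shift (50-position) or sampling nulls by
  two-sided Mann–Whitney tests, with 50-kb distance-interval grouping and
  20-bin least-squares/Spearman correlation summaries.
* **Regulatory domains (TRDs).** Maximal runs of ≥ 2 contiguous expressed
  genes sharing a category under relaxed thresholds (|log2FC| > 0.5,
  p < 0.05), with contiguous-pair sampling nulls (5000 iterations),
  concordant-enhancer association within ±50 kb, and descriptives.
* **3D structure.** Per-bin directionality index over ±250 kb windows,
  DI = sign(B−A)·((A−E)²/E + (B−E)²/E) with E = (A+B)/2; TAD co-regulation
  (per-TAD fraction of upregulated genes vs a gene-permutation null, 500
  iterations); TAD-border insulation of contiguous-pair and
  enhancer–gene correlations; proportional and boundary metaplots;
  mirrored-coordinate and 10-Mb-shift domain randomizations.
* **Footprints.** Motif enrichment Enr =
  (footprints[motif]/footprints[total]) /
  (footprints_bg[motif]/footprints_bg[total]) with two-sided Fisher exact
  tests, differential enrichment between accessibility categories, Tn5
  cut-site extraction (+4/−5 shifts, sub-100-bp fragments) and per-bp
  footprint profiles.

## Worked example

```python
from coregdom import domains, regulation
from coregdom.simulate import SimulationConfig, default_planted_domains, \
    generate_genome, plant_regulation

cfg = SimulationConfig(seed=1, n_chromosomes=2, genes_per_chromosome=1000,
                       planted_domains=default_planted_domains(30))
genes, truth = plant_regulation(generate_genome(cfg), cfg)
genes = regulation.classify_genes(genes)
trds = domains.call_trds(genes)
print(len(truth.domains), len(trds), trds["n_genes"].mean().round(2),
      trds["size_kb"].mean().round(1))
```

prints

```
30 30 2.3 186.8
```

— all 30 planted co-regulated domains are recovered as called TRDs,
averaging 2.3 genes and ~187 kb under the default synthetic geometry
(50-kb median TSS spacing). A full pipeline run
(`coregdom run --outdir out/`) chains simulation, classification,
neighborhood summaries, TRD calling, TAD co-regulation, directionality
index and footprint enrichment, writing TSVs plus a `provenance.json` with
the configuration hash and all stage seeds; re-running the same
configuration reproduces every output byte-identically.

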