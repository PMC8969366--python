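# annoquant

**How much does the choice of gene annotation change RNA-seq gene-level
quantification?** `annoquant` is a reusable benchmarking pipeline for
answering that question. It is aimed at bioinformaticians who quantify bulk
(or single-cell) RNA-seq by counting mapped fragments to annotated genes and
want to measure — rather than assume — the impact of switching between
annotation releases (e.g. Ensembl vs. RefSeq dialect GTFs).

The pipeline covers, end to end:

- **Annotation diffing** — parse GTFs into gene models, compute exon-union
  *effective gene lengths* (`len(g) = |⋃ exons(g)|` in bases), transcriptome
  sizes (`Σ_g len(g)`), Venn-region tables of genes common or unique across
  2–3 annotations under one-to-one identifier matching, and per-gene
  log2 effective-length ratios.
- **Fragment counting** — featureCounts-style assignment: a fragment is
  counted to a gene if any aligned block overlaps any exon of that gene by
  ≥1 base (unstranded); fragments hitting two or more genes are unassigned
  (ambiguous), fragments hitting no exon are unassigned (no feature).
  Multi-mapping fragments are first resolved to a single candidate: a unique
  exon-overlapping location wins; otherwise the first location in canonical
  order (chromosome order, then start). Multi-mappers are also classified as
  hitting multiple genes / one gene / no exon.
- **Normalization** — voom-style log2CPM
  (`log2((count + 0.5) / (libsize·factor + 1) · 10⁶)`) under library-size,
  quantile, or TMM (trimmed-mean-of-M-values) normalization, converted to
  log2FPKM by subtracting `log2(effective_length / 1000)`; plus the common
  expression filter (keep genes with ≥0.5 CPM in ≥4 libraries).
- **Titration assessment** — for SEQC-style designs where samples C and D
  are 3:1 and 1:3 mixtures of reference samples A and B, the expected
  C-vs-D log2 fold-change given the A-vs-B fold-change *x* is

  ```
  E(x) = log2( (3·2^x + 1) / (2^x + 3) )
  ```

  (bounded by ±log2 3). Each gene's observed C-vs-D fold-change is scored
  against `E(x)` with a mean squared error, and each gene is flagged for
  titration monotonicity (A ≥ C ≥ D ≥ B or the reverse ordering).
- **Truth validation** — Pearson correlation per sample between
  replicate-averaged RNA-seq log2 expression and external truth tables:
  RT-PCR-like (one row per gene, log2-transformed on read) and
  microarray-like (multi-probe, reduced to the representative probe with the
  highest mean expression across samples).
- **Synthetic data** — a seeded generator that emulates the study structure
  (2–3 annotations with partially shared genes and divergent lengths, 16
  libraries = 4 samples × 4 replicates with linear 3:1 / 1:3 mixing,
  negative-binomial count noise, fragment files with intronic/intergenic/
  multi-mapping placements, RT-PCR- and microarray-like truth tables), with
  full bookkeeping so every stage can be checked against ground truth.

## Worked example

```python
import annoquant as aq
from annoquant.simulate import SyntheticConfig, generate_annotations, generate_counts

cfg = SyntheticConfig(seed=7, n_genes=1000, dispersion=0.1)
anns, maps, book = generate_annotations(cfg)
ann = anns[0]
print("annotation:", ann.name, "genes:", len(ann))
print("transcriptome size (bases):", aq.transcriptome_size(ann))

cm, true_log2 = generate_counts(cfg, ann)
expr = aq.log2fpkm(aq.log2cpm(cm), cm.lengths)
result = aq.assess_titration(expr, cfg.design())
print(f"titration MSE: {result.mse:.4f}")
print(f"monotone fraction: {result.monotone_fraction:.3f}")

regions = aq.overlap_counts(anns, maps)
```

prints

```
annotation: ensembl_like genes: 784
transcriptome size (bases): 1033788
titration MSE: 0.1291
monotone fraction: 0.676
```

The MSE of 0.13 says that, at negative-binomial dispersion 0.1, each gene's
observed C-vs-D log2 fold-change deviates from the expected titration curve
by ~0.36 on average; at dispersion 0 the same pipeline returns an MSE of
~10⁻³⁰ and a monotone fraction of exactly 1.0, because the mixtures are then
exact. The Venn table in `regions` reproduces the generator's configured
sharing structure (600 genes common to all three annotations here).

## Command line

```bash
annoquant simulate --seed 1 --n-genes 2000 --fragments --out bundle/
annoquant annot-stats bundle/ensembl_like.gtf --out-summary summary.json
annoquant count bundle/ensembl_like.gtf --fragments A_1=bundle/ensembl_like.A_1.bed \
    --out-counts counts.tsv
annoquant normalize counts.tsv --method TMM --out expr.tsv
annoquant titrate expr.tsv --out titration.tsv
annoquant run-all --synthetic --seed 1 --out benchmark_out/
```

`run-all` writes per-annotation gene tables, count matrices, normalized
expression, titration tables, correlation reports and a `report.json`
summary; it is byte-for-byte reproducible for a fixed seed.

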