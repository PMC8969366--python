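# Methods

## Problem and pipeline

Gene-level RNA-seq quantification counts mapped fragments (read pairs) to
annotated genes, so every downstream number depends on the annotation used.
`annoquant` measures that dependence with a fixed pipeline:

1. parse each annotation (GTF) into gene models — a gene is its set of exon
   intervals plus identifiers and a biotype;
2. count fragments to genes under featureCounts semantics;
3. convert counts to normalized log2 expression;
4. score quantification accuracy against internal truth (titration
   monotonicity of mixture samples) and external truth (RT-PCR-like and
   microarray-like tables);
5. compare accuracy across annotations on matched gene sets.

## Coordinates and gene models

GTF rows are 1-based inclusive; internally every interval is 0-based
half-open, which makes lengths `end − start` and removes off-by-one
ambiguity. Only `exon` rows define quantification structure (`gene` rows
seed metadata); genes without any exon row are excluded and counted. The
*effective length* of a gene is the number of unique bases in the union of
its exons, computed per chromosome and summed; `collapse_exons` merges
overlapping **and adjacent** exons into the canonical minimal disjoint
representation, which never changes effective length. Strand is stored but
ignored in all overlap and length computations: the benchmark's libraries
are unstranded. Transcriptome size is the per-gene sum of effective
lengths, so bases shared by overlapping genes count once per gene — this is
the natural reading of "sum of effective gene lengths" and is flagged in
reports because the alternative (genomic union) differs when genes overlap.

## Cross-annotation matching

Genes are matched by identifier only, through explicit two-column mapping
tables (no live database, no coordinate matching). Comparisons restrict to
pairs that are one-to-one after dropping rows referring to absent genes;
residual many-to-many genes are excluded and reported. For three-way Venn
regions, a gene group counts as common to all three only when the three
pairwise matches close transitively; non-transitive triples are demoted to
the first consistent pairwise region (in annotation order) and logged. This
is a conservative convention; the alternative (treating any chain as a
triple) would overstate concordance.

## Fragment counting

A fragment is assigned to a gene if any of its aligned reference blocks
overlaps any exon of that gene by at least one base (featureCounts'
default). Fragments overlapping exons of ≥2 genes are unassigned-ambiguous
(not counted to any gene); fragments overlapping no exon are
unassigned-no-feature. Multi-mapping fragments (several candidate
locations) are resolved before assignment: if exactly one candidate
overlaps any gene's exon it is chosen; among several, the first in
canonical order; with none, the first in canonical order overall. Canonical
order is chromosome order as listed in the annotation, then leftmost start,
then input order — the original aligner index order is not available to a
re-implementation, so determinism is the contract. Multi-mappers are also
classified by the genes all their candidates collectively hit (≥2 genes /
exactly one gene / no exon), mirroring the assignment-ambiguity analysis.
Downstream library sizes are total *assigned* fragments (count-matrix
column sums); using total mapped fragments instead is a configuration
choice the reports note.

The SAM reader supports the minimal subset the pipeline needs (QNAME, FLAG,
RNAME, POS, CIGAR; secondary alignments as extra candidates; M/=/X consume
reference, N and D split blocks, I/S/H/P do not). It is deliberately
hand-written because headerless SAM must parse and records must group by
QNAME into multi-candidate fragments; its block extraction is cross-checked
against pysam in the test suite.

## Normalization and filtering

log2CPM uses voom-style offsets: `log2((count + 0.5) / (libsize·f + 1) ·
10⁶)`, with normalization factor `f` = 1 (library size), TMM factors, or 1
followed by quantile normalization of the log-scale matrix. The prior count
0.5 avoids log of zero; the +1 library-size offset keeps values finite for
empty libraries. A plain variant without the +1 offset is available
(`voom_offsets=False`). log2FPKM subtracts `log2(effective_length/1000)`.

TMM follows the published trimmed-mean-of-M-values definition: reference =
library whose upper-quartile CPM is closest to the mean upper-quartile;
per-library M (log2 expression ratio) and A (average log2 abundance) over
genes positive in both libraries; rank-trim 30% of M and 5% of A from each
tail; factor = 2^(mean of surviving M weighted by inverse asymptotic
binomial variance); factors rescaled to geometric mean 1. The
implementation agrees with an independent step-by-step oracle to 1e-8 in
the tests (and with the reference Bioconductor implementation to machine
precision). One caveat: TMM is only *approximately* invariant to rescaling
one library together with its size, because the variance weights are not
scale-free; the tests assert near-invariance.

Quantile normalization replaces each column's sorted values with the
across-column rank means; ties within a column receive the mean of the rank
means they span ("ties = mean" convention; the choice only matters for
discrete data). It is idempotent and row-permutation-equivariant.

The expression filter keeps genes with CPM ≥ 0.5 (prior 0, raw library
sizes — filtering precedes normalization) in ≥ 4 libraries; both bounds
inclusive.

## Titration statistic

For mixtures C = p·A + (1−p)·B and D = q·A + (1−q)·B on the linear scale
(defaults p = 0.75, q = 0.25), a gene with A-vs-B log2 fold-change x has
expected C-vs-D log2 fold-change

    E(x) = log2( (p·2^x + 1−p) / (q·2^x + 1−q) )
         = log2( (3·2^x + 1) / (2^x + 3) )   at the defaults,

antisymmetric in x and bounded by ±log2 3. Replicates are averaged on the
log2 scale before fold-changes (matching how the plotted expression values
are averaged); linear-scale averaging is available behind a flag. The MSE
is the mean of (observed_CD − E(x))² over all genes with finite values (the
count is reported); genes are additionally flagged monotone when the four
sample means satisfy A ≥ C ≥ D ≥ B or A ≤ C ≤ D ≤ B (non-strict, so flat
genes are monotone). The gene set is selectable: all genes, filtered genes,
or genes common to all annotations after filtering.

## Truth validation

RT-PCR-like tables are one row per gene and are log2-transformed on read by
default (raw RT-PCR values arrive linear); microarray-like tables carry
probes and are consumed as final log2 values (background correction and
array normalization are upstream and out of scope). Multi-probe genes are
reduced to the representative probe with the highest mean expression across
samples (exact ties break to the smallest probe id). Validation is the
per-sample Pearson correlation across matched genes between
replicate-averaged RNA-seq log2 expression (after the expression filter)
and the truth values, reported per platform × normalization × gene-set
mode. Zero-variance sides yield an undefined correlation with a warning
rather than an arbitrary number.

## Synthetic study conditions

The generator emulates the benchmark's structure at desk scale; defaults
are fixed once as the study conditions:

- **2,000 universe genes**, three annotations sharing 60% of genes fully
  and 15% pairwise; shared genes keep identifiers and biotypes but their
  exon lengths in the non-reference annotations are scaled by 2^N(0, 0.5),
  giving the configured log2 length-ratio distribution.
- **16 libraries** = 4 samples × 4 replicates; C and D are exact 3:1 and
  1:3 linear mixtures of A and B.
- **Expected counts ∝ concentration × effective length** (so FPKM tracks
  concentration), scaled to 10⁶ expected assigned fragments per library —
  the same per-gene depth as ~20M fragments over ~40k genes at full scale.
  Sample B's concentrations are rescaled so both reference samples carry
  equal total length-weighted abundance; the A/B expectations are then
  quantized to integers congruent mod 4 with balanced totals, so the C/D
  expectations are integers, every library's total is identical, and at
  dispersion 0 the counts *are* the expectations. This makes noiseless
  recovery exact: titration MSE ~10⁻³⁰ (the 0.5 prior mixes linearly and
  cancels from the statistic) and monotone fraction exactly 1.
- **Negative-binomial noise** with Var = μ + φμ² (default φ = 0.1); φ = 0
  degenerates to the deterministic expectations rather than Poisson, which
  is what makes exact-recovery tests possible.
- **Fragment simulation**: 200-base single-block fragments placed uniformly
  within exons of genes drawn ∝ concentration × length, plus configured
  fractions of intronic and intergenic placements (5% each) and
  multi-mapping fragments (5%) whose decoy candidate is intergenic — so
  resolution recovers the true gene and the placed-fragment truth is
  exactly recoverable when genes do not overlap.
- **Truth tables**: a covered subset (40%) of genes gets truth = true log2
  value + N(0, 0.25²); the microarray table adds 1–3 probes per gene with
  constant per-probe offsets ~N(0,1) so representative-probe selection is
  exercised.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence-level effects (mappability, GC,
positional bias), mRNA-fraction differences between reference samples that
distort real titration, annotation errors correlated with expression,
overlapping-gene structure beyond simple pairwise exon overlap, and real
probe–gene mismatch on arrays.

## Numerical and design notes

- All randomness flows from one integer seed through named, FNV-hashed
  spawned streams; a fixed seed gives byte-identical bundles and benchmark
  outputs (floats are written with `%.10g`).
- Interval queries use an interval tree per chromosome; equivalence with
  the O(n·m) brute-force assigner is asserted on random toys.
- Quantile positions use linear interpolation (numpy default); boxplot
  whiskers are Tukey 1.5·IQR clipped to the data.
- Degenerate inputs: empty GTF → empty annotation with a warning; zero
  library size → error naming the library; a library sharing no positive
  genes with the TMM reference → factor 1 with a warning; fewer than three
  matched genes → validation error.
- Known limitations: no transcript/isoform models, no strand-aware
  counting, no CIGAR clipping subtleties beyond M/=/X/N/D/I/S/H/P, no
  probabilistic rescue of ambiguous multi-mappers, no array preprocessing.
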