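"""Synthetic SEQC-like data: annotations, counts, fragments and truth tables.

The generator emulates the structure the benchmark needs without any
external downloads: two or three annotations sharing a configurable
fraction of genes (with divergent exon structures), a 16-library design of
four samples x four replicates where C and D are 3:1 and 1:3 linear
mixtures of A and B, negative-binomial count noise, fragment files that
exercise the counter's failure modes (intronic, intergenic, multi-mapping
placements), and RT-PCR-like / multi-probe microarray-like truth tables.

Every random draw flows from ``SyntheticConfig.seed`` through spawned
``numpy`` generators, so a fixed seed yields byte-identical bundles.
Bookkeeping tables (true Venn regions, per-annotation effective lengths,
drawn length-divergence factors, placed-fragment truth) let tests check
each pipeline stage against the generator's ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    collapse_exons,
    effective_length,
    write_gtf,
)
from .compare import IdentifierMap
from .counting import AlignedBlock, CountMatrix, FragmentAlignment
from .titration import MixtureDesign
from .validation import TruthTable

_ID_STYLES = ("ENS{:06d}", "GID{:d}", "OLD{:06d}")
_ANN_NAMES = ("ensembl_like", "refseq_like", "refseq_old_like")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate a desk-scale SEQC design: 2,000 genes, 16 libraries
    (4 samples x 4 replicates, C/D mixed 3:1 and 1:3), one million expected
    assigned fragments per library (so per-gene depth matches the real
    libraries' ~20M fragments over ~40k genes), and moderate
    negative-binomial dispersion.
    """

    seed: int = 0
    n_genes: int = 2000  # universe size across annotations
    n_annotations: int = 3
    shared_fraction: float = 0.6  # genes present in every annotation
    pairwise_fraction: float = 0.15  # genes present in exactly two (split over pairs)
    biotype_proportions: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.55,
            "lncRNA": 0.25,
            "pseudogene": 0.15,
            "miRNA": 0.05,
        }
    )
    mean_exons: float = 3.0  # n_exons = 1 + Poisson(mean_exons - 1)
    exon_length_range: tuple = (100, 800)
    intron_length_range: tuple = (200, 2000)
    intergenic_gap_range: tuple = (1000, 5000)
    n_chroms: int = 4
    length_divergence_sd: float = 0.5  # sd of log2 length factor for shared genes
    overlap_pair_fraction: float = 0.0  # fraction of genes overlapping a neighbour
    baseline_log2_mean: float = 4.0  # log2 concentration in samples A and B
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1  # NB: Var = mu + phi mu^2; 0 => deterministic
    library_size: int = 1_000_000
    replicates: int = 4
    p_mix: float = 0.75  # fraction of A in sample C
    q_mix: float = 0.25  # fraction of A in sample D
    truth_coverage: float = 0.4
    truth_sigma: float = 0.25  # Gaussian noise on log2 truth values
    max_probes: int = 3  # microarray probes per covered gene (1..max)
    frac_intergenic: float = 0.05
    frac_intronic: float = 0.05
    frac_multimapper: float = 0.05
    fragments_per_library: int = 5000
    fragment_length: int = 200

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "pairwise_fraction", "truth_coverage",
                     "frac_intergenic", "frac_intronic", "frac_multimapper"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.shared_fraction + self.pairwise_fraction > 1:
            raise ValueError("shared_fraction + pairwise_fraction must not exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 2 <= self.n_annotations <= 3:
            raise ValueError("n_annotations must be 2 or 3")
        if abs(sum(self.biotype_proportions.values()) - 1) > 1e-9:
            raise ValueError("biotype proportions must sum to 1")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.overlap_pair_fraction > 0 and self.n_genes < 2:
            raise ValueError("overlap pairs need at least two genes")

    def design(self) -> MixtureDesign:
        design = MixtureDesign(
            proportions={
                "A": (1.0, 0.0),
                "B": (0.0, 1.0),
                "C": (self.p_mix, 1 - self.p_mix),
                "D": (self.q_mix, 1 - self.q_mix),
            }
        )
        design.replicate_map = {
            f"{s}_{r + 1}": s for s in ("A", "B", "C", "D") for r in range(self.replicates)
        }
        return design

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, abs(hash_stream(stream))])


def hash_stream(name: str) -> int:
    # stable (non-salted) stream id for child seeds
    h = 2166136261
    for ch in name.encode():
        h = (h ^ ch) * 16777619 % (2 ** 31)
    return h


@dataclass
class Bookkeeping:
    """Ground truth the generator records for every pipeline stage."""

    membership: list[tuple] = field(default_factory=list)  # per universe gene: annotation names
    biotypes: list[str] = field(default_factory=list)  # per universe gene
    venn_regions: dict = field(default_factory=dict)  # frozenset(names) -> count
    venn_by_biotype: dict = field(default_factory=dict)  # biotype -> region dict
    effective_lengths: dict = field(default_factory=dict)  # ann name -> {universe idx: bases}
    log2_length_factors: dict = field(default_factory=dict)  # ann name -> {idx: log2 factor}
    overlap_pairs: dict = field(default_factory=dict)  # ann name -> list of (gid, gid)
    gene_ids: dict = field(default_factory=dict)  # ann name -> {universe idx: gene_id}


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    annotations: list[AnnotationSet]
    maps: dict  # (nameA, nameB) -> IdentifierMap
    bookkeeping: Bookkeeping
    counts: dict  # ann name -> CountMatrix
    true_log2_expression: dict  # ann name -> DataFrame (gene x sample, log2 concentration)
    design: MixtureDesign
    truth_tables: dict  # ann name -> {platform: TruthTable}
    truth_maps: dict  # ann name -> IdentifierMap (annotation id -> truth id)
    fragments: dict = field(default_factory=dict)  # ann name -> {library: [FragmentAlignment]}
    placed_truth: dict = field(default_factory=dict)  # ann name -> {library: {gene: n placed}}


# ---------------------------------------------------------------------------
# Annotations


def _draw_gene_structure(cfg: SyntheticConfig, rng: np.random.Generator):
    n_exons = 1 + rng.poisson(max(cfg.mean_exons - 1, 0))
    lo, hi = cfg.exon_length_range
    exon_lengths = rng.integers(lo, hi + 1, size=n_exons)
    ilo, ihi = cfg.intron_length_range
    introns = rng.integers(ilo, ihi + 1, size=max(n_exons - 1, 0))
    return list(map(int, exon_lengths)), list(map(int, introns))


def generate_annotations(cfg: SyntheticConfig):
    """Build 2-3 annotations with shared genes, plus maps and bookkeeping.

    Returns (annotations, maps, bookkeeping). Shared genes keep biotype and
    identifier linkage across annotations but their exon lengths in
    annotations other than the first are scaled by 2^N(0, sd) factors.
    """
    rng = cfg._rng("annotations")
    names = list(_ANN_NAMES[: cfg.n_annotations])
    n = cfg.n_genes

    # membership patterns
    n_all = round(cfg.shared_fraction * n)
    pairs = [(i, j) for i in range(cfg.n_annotations) for j in range(i + 1, cfg.n_annotations)]
    n_pair_total = round(cfg.pairwise_fraction * n)
    membership: list[tuple[int, ...]] = []
    for _ in range(n_all):
        membership.append(tuple(range(cfg.n_annotations)))
    for k in range(n_pair_total):
        membership.append(pairs[k % len(pairs)])
    k = 0
    while len(membership) < n:
        membership.append((k % cfg.n_annotations,))
        k += 1
    rng.shuffle(membership)

    biotype_names = list(cfg.biotype_proportions)
    probs = np.array([cfg.biotype_proportions[b] for b in biotype_names])
    biotypes = [biotype_names[i] for i in rng.choice(len(biotype_names), size=n, p=probs)]

    structures = [_draw_gene_structure(cfg, rng) for _ in range(n)]
    factors = rng.normal(0.0, cfg.length_divergence_sd, size=(n, cfg.n_annotations))
    factors[:, 0] = 0.0  # first annotation is the reference structure

    book = Bookkeeping(
        membership=[tuple(names[a] for a in m) for m in membership],
        biotypes=biotypes,
    )
    for m, bt in zip(book.membership, biotypes):
        key = frozenset(m)
        book.venn_regions[key] = book.venn_regions.get(key, 0) + 1
        per_bt = book.venn_by_biotype.setdefault(bt, {})
        per_bt[key] = per_bt.get(key, 0) + 1

    annotations = []
    for a, name in enumerate(names):
        ann = AnnotationSet(name=name, chrom_order=[f"chr{c + 1}" for c in range(cfg.n_chroms)])
        cursors = {c: 0 for c in ann.chrom_order}
        book.effective_lengths[name] = {}
        book.log2_length_factors[name] = {}
        book.overlap_pairs[name] = []
        book.gene_ids[name] = {}
        member_idx = [i for i in range(n) if a in membership[i]]
        prev_by_chrom: dict[str, GeneModel] = {}
        for order, i in enumerate(member_idx):
            exon_lengths, introns = structures[i]
            scale = 2.0 ** factors[i, a]
            lengths = [max(20, round(L * scale)) for L in exon_lengths]
            chrom = ann.chrom_order[order % cfg.n_chroms]
            glo, ghi = cfg.intergenic_gap_range
            start = cursors[chrom] + int(rng.integers(glo, ghi + 1))
            prev_gene = prev_by_chrom.get(chrom)
            overlap_here = (
                cfg.overlap_pair_fraction > 0
                and prev_gene is not None
                and rng.random() < cfg.overlap_pair_fraction
            )
            if overlap_here:
                last_exon = max(prev_gene.exons, key=lambda e: e.end)
                start = max(last_exon.start, last_exon.end - min(50, len(last_exon) - 1))
            exons = []
            pos = start
            for j, L in enumerate(lengths):
                exons.append(GenomicInterval(chrom, pos, pos + L, "+"))
                pos += L
                if j < len(introns):
                    pos += max(50, round(introns[j] * scale))
            gid = _ID_STYLES[a].format(i)
            gene = GeneModel(
                gene_id=gid,
                exons=exons,
                symbol=f"SYM{i}",
                biotype=biotypes[i],
                secondary_ids={"universe": str(i)},
            )
            ann.add(gene)
            cursors[chrom] = max(cursors[chrom], pos)
            book.effective_lengths[name][i] = effective_length(gene)
            book.log2_length_factors[name][i] = float(factors[i, a])
            book.gene_ids[name][i] = gid
            if overlap_here:
                book.overlap_pairs[name].append((prev_gene.gene_id, gid))
            prev_by_chrom[chrom] = gene
        annotations.append(ann)

    maps = {}
    for ai, aj in pairs:
        ni, nj = names[ai], names[aj]
        shared = [
            i for i in range(n) if ai in membership[i] and aj in membership[i]
        ]
        maps[(ni, nj)] = IdentifierMap(
            pairs=[(_ID_STYLES[ai].format(i), _ID_STYLES[aj].format(i)) for i in shared],
            namespaces=(ni, nj),
        )
    return annotations, maps, book


# ---------------------------------------------------------------------------
# Counts


def _draw_abundance(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Linear-scale concentrations for samples A and B, shape (n, 2)."""
    za = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    zb = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    return np.exp2(np.column_stack([za, zb]))


def _quantize_reference_counts(mu_a: np.ndarray, mu_b: np.ndarray, step: int = 4):
    """Integer reference expectations with exact integer mixtures.

    Rounds the A expectations to integers and the B expectations to the
    nearest integer congruent to A's modulo ``step`` (4 for quarter
    mixtures), then nudges the largest B genes by +-step so both samples
    carry exactly the same total. The 3:1 and 1:3 mixtures of the result
    are integers and all four samples sum identically, so per-library CPM
    denominators are equal by construction.
    """
    ka = np.round(mu_a).astype(np.int64)
    kb = ka + step * np.round((mu_b - ka) / step).astype(np.int64)
    kb = np.where(kb < 0, ka % step, kb)
    diff = int(ka.sum() - kb.sum())  # multiple of step by congruence
    n_adj = abs(diff) // step
    sign = 1 if diff > 0 else -1
    if n_adj:
        order = np.argsort(-kb, kind="stable")
        i = 0
        for g in np.nditer(order):
            if n_adj == 0:
                break
            if sign < 0 and kb[g] < step:
                continue
            kb[g] += sign * step
            n_adj -= 1
            i += 1
    return ka, kb


def generate_counts(
    cfg: SyntheticConfig,
    annotation: AnnotationSet,
    abundance: dict | None = None,
):
    """Simulate a CountMatrix for one annotation plus the true expression.

    Expected fragment counts are proportional to concentration x effective
    length; sample B's concentrations are rescaled so that both reference
    samples carry the same total length-weighted abundance, which makes the
    C/D mixing identity exact on expectations and keeps per-library totals
    comparable. The reference expectations are quantized to integers that
    are congruent modulo 1/q (4 at the default 3:1 / 1:3 design) and whose
    totals balance exactly, so the mixture expectations are themselves
    integers and every library carries the same total: at dispersion 0 the
    counts ARE those expectations and the titration structure is exact.
    Counts are NB(mean, dispersion) with Var = mu + phi mu^2; dispersion 0
    degenerates to the deterministic expectations.

    ``abundance`` optionally maps gene_id -> (conc_A, conc_B) to share
    concentrations across annotations; otherwise they are drawn here.
    Returns (CountMatrix, true log2 concentration DataFrame gene x sample).
    """
    rng = cfg._rng(f"counts:{annotation.name}")
    gene_ids = sorted(annotation.genes)
    lengths = {g: effective_length(annotation.genes[g]) for g in gene_ids}
    L = np.array([lengths[g] for g in gene_ids], dtype=float)
    if abundance is None:
        ab = _draw_abundance(cfg, len(gene_ids), rng)
    else:
        ab = np.array([abundance[g] for g in gene_ids], dtype=float)
    # equalize total length-weighted abundance between the reference samples
    ab = ab.copy()
    ab[:, 1] *= (ab[:, 0] @ L) / (ab[:, 1] @ L)

    total = ab[:, 0] @ L  # identical for every sample by construction
    mu_a = ab[:, 0] * L / total * cfg.library_size
    mu_b = ab[:, 1] * L / total * cfg.library_size
    ka, kb = _quantize_reference_counts(mu_a, mu_b)

    design = cfg.design()
    samples = design.samples
    mu = np.empty((len(gene_ids), len(samples)))
    conc = np.empty((len(gene_ids), len(samples)))
    for s, sample in enumerate(samples):
        pa, pb = design.proportions[sample]
        mu[:, s] = pa * ka + pb * kb
        conc[:, s] = pa * ab[:, 0] + pb * ab[:, 1]

    libraries = list(design.replicate_map)
    counts = np.empty((len(gene_ids), len(libraries)), dtype=np.int64)
    for j, lib in enumerate(libraries):
        s = samples.index(design.replicate_map[lib])
        m = mu[:, s]
        if cfg.dispersion == 0:
            counts[:, j] = np.round(m).astype(np.int64)
        else:
            r = 1.0 / cfg.dispersion
            safe = np.maximum(m, 1e-8)
            counts[:, j] = rng.negative_binomial(r, r / (r + safe))
    cm = CountMatrix(
        gene_ids=gene_ids,
        library_ids=libraries,
        counts=counts,
        lengths=lengths,
    )
    true_log2 = pd.DataFrame(np.log2(conc), index=gene_ids, columns=samples)
    return cm, true_log2


# ---------------------------------------------------------------------------
# Fragments


def generate_fragments(cfg: SyntheticConfig, annotation: AnnotationSet, abundance: dict | None = None):
    """Simulate per-library fragment alignments for one annotation.

    Returns (fragments, placed_truth): ``fragments`` maps library_id to a
    list of FragmentAlignment; ``placed_truth`` maps library_id to per-gene
    placed exonic fragment counts (what an exact counter should recover when
    no genes overlap). Noise fragments are intronic or intergenic
    (no-feature); multi-mapping fragments pair the true exonic location with
    an intergenic decoy candidate.
    """
    rng = cfg._rng(f"fragments:{annotation.name}")
    gene_ids = sorted(annotation.genes)
    collapsed = {g: collapse_exons(annotation.genes[g]) for g in gene_ids}
    L = np.array([effective_length(collapsed[g]) for g in gene_ids], dtype=float)
    if abundance is None:
        ab = _draw_abundance(cfg, len(gene_ids), rng)
    else:
        ab = np.array([abundance[g] for g in gene_ids], dtype=float)
    ab = ab.copy()
    ab[:, 1] *= (ab[:, 0] @ L) / (ab[:, 1] @ L)

    chrom_max = {c: 0 for c in annotation.chrom_order}
    introns: list[tuple[str, int, int]] = []
    for g in gene_ids:
        exons = collapsed[g].exons
        for ex in exons:
            chrom_max[ex.chrom] = max(chrom_max[ex.chrom], ex.end)
        for e1, e2 in zip(exons, exons[1:]):
            if e1.chrom == e2.chrom and e2.start - e1.end >= cfg.fragment_length:
                introns.append((e1.chrom, e1.end, e2.start))

    design = cfg.design()
    fragments: dict[str, list[FragmentAlignment]] = {}
    placed_truth: dict[str, dict[str, int]] = {}

    def exonic_block(gidx: int) -> AlignedBlock:
        exons = collapsed[gene_ids[gidx]].exons
        weights = np.array([len(e) for e in exons], dtype=float)
        ex = exons[rng.choice(len(exons), p=weights / weights.sum())]
        flen = min(cfg.fragment_length, len(ex))
        start = int(rng.integers(ex.start, ex.end - flen + 1))
        return AlignedBlock(ex.chrom, start, start + flen)

    def intergenic_block() -> AlignedBlock:
        chrom = annotation.chrom_order[int(rng.integers(len(annotation.chrom_order)))]
        base = chrom_max[chrom] + 10_000
        start = base + int(rng.integers(0, 50_000))
        return AlignedBlock(chrom, start, start + cfg.fragment_length)

    def intronic_block() -> AlignedBlock:
        if not introns:
            return intergenic_block()
        chrom, lo, hi = introns[int(rng.integers(len(introns)))]
        start = int(rng.integers(lo, hi - cfg.fragment_length + 1))
        return AlignedBlock(chrom, start, start + cfg.fragment_length)

    for lib, sample in design.replicate_map.items():
        pa, pb = design.proportions[sample]
        conc = pa * ab[:, 0] + pb * ab[:, 1]
        gene_p = conc * L
        gene_p = gene_p / gene_p.sum()
        frags: list[FragmentAlignment] = []
        truth = {g: 0 for g in gene_ids}
        categories = rng.choice(
            4,
            size=cfg.fragments_per_library,
            p=[
                cfg.frac_intergenic,
                cfg.frac_intronic,
                cfg.frac_multimapper,
                1 - cfg.frac_intergenic - cfg.frac_intronic - cfg.frac_multimapper,
            ],
        )
        gene_draws = rng.choice(len(gene_ids), size=cfg.fragments_per_library, p=gene_p)
        for fid, (cat, gidx) in enumerate(zip(categories, gene_draws)):
            name = f"{lib}:f{fid}"
            if cat == 0:
                cands = [[intergenic_block()]]
            elif cat == 1:
                cands = [[intronic_block()]]
            elif cat == 2:
                real = exonic_block(gidx)
                truth[gene_ids[gidx]] += 1
                cands = [[intergenic_block()], [real]]  # decoy listed first
            else:
                truth[gene_ids[gidx]] += 1
                cands = [[exonic_block(gidx)]]
            frags.append(FragmentAlignment(fragment_id=name, candidates=cands, library_id=lib))
        fragments[lib] = frags
        placed_truth[lib] = truth
    return fragments, placed_truth


def write_fragments_bed(fragments: list[FragmentAlignment], path) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            for cand in frag.candidates:
                for block in cand:
                    fh.write(f"{block.chrom}\t{block.start}\t{block.end}\t{frag.fragment_id}\n")


def write_fragments_sam(fragments: list[FragmentAlignment], path, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for frag in fragments:
            for c, cand in enumerate(frag.candidates):
                flag = 0 if c == 0 else 256
                for block in cand:
                    cigar = f"{block.end - block.start}M"
                    fh.write(
                        f"{frag.fragment_id}\t{flag}\t{block.chrom}\t{block.start + 1}\t"
                        f"255\t{cigar}\t*\t0\t0\t*\t*\n"
                    )


# ---------------------------------------------------------------------------
# Truth tables


def generate_truth_tables(
    cfg: SyntheticConfig,
    true_expression: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """RT-PCR-like and microarray-like truth tables from true log2 expression.

    Covered genes (a seeded random subset of ``truth_coverage`` of the rows)
    get truth = true value + N(0, sigma^2) per sample. The microarray table
    carries 1..max_probes probes per gene with constant per-probe offsets so
    representative-probe selection is exercised. Returned tables hold log2
    values; truth gene ids are ``T<row id>``.
    """
    if rng is None:
        rng = cfg._rng("truth")
    genes = list(true_expression.index)
    samples = list(true_expression.columns)
    n_cov = round(cfg.truth_coverage * len(genes))
    covered = sorted(rng.choice(len(genes), size=n_cov, replace=False))
    truth_ids = {genes[i]: f"T{genes[i]}" for i in covered}

    rt_rows = {}
    ma_rows = {}
    for i in covered:
        g = genes[i]
        base = true_expression.loc[g].to_numpy()
        noise = rng.normal(0, cfg.truth_sigma, size=len(samples)) if cfg.truth_sigma > 0 else 0.0
        rt_rows[truth_ids[g]] = base + noise
        n_probes = int(rng.integers(1, cfg.max_probes + 1))
        offsets = rng.normal(0, 1.0, size=n_probes)
        for pnum in range(n_probes):
            pnoise = rng.normal(0, cfg.truth_sigma, size=len(samples)) if cfg.truth_sigma > 0 else 0.0
            ma_rows[(truth_ids[g], f"P{pnum}")] = base + offsets[pnum] + pnoise

    rtpcr = TruthTable(
        platform="rtpcr",
        data=pd.DataFrame.from_dict(rt_rows, orient="index", columns=samples),
    )
    ma_df = pd.DataFrame.from_dict(ma_rows, orient="index", columns=samples)
    ma_df.index = pd.MultiIndex.from_tuples(ma_df.index, names=["gene_id", "probe_id"])
    microarray = TruthTable(platform="microarray", data=ma_df)
    truth_map = IdentifierMap(
        pairs=[(g, t) for g, t in truth_ids.items()], namespaces=("rnaseq", "truth")
    )
    return {"rtpcr": rtpcr, "microarray": microarray}, truth_map


# ---------------------------------------------------------------------------
# Bundle


def generate_bundle(cfg: SyntheticConfig, with_fragments: bool = False) -> SyntheticBundle:
    """Generate the full synthetic study: annotations, counts, truth tables.

    Gene concentrations are drawn once per universe gene and shared across
    annotations, as the same RNA samples are being quantified against each
    annotation. ``with_fragments`` additionally simulates per-library
    fragment alignments (slower; counts matrices are always produced).
    """
    annotations, maps, book = generate_annotations(cfg)
    rng = cfg._rng("abundance")
    universe_ab = _draw_abundance(cfg, cfg.n_genes, rng)

    counts = {}
    true_expr = {}
    truth_tables = {}
    truth_maps = {}
    fragments = {}
    placed_truth = {}
    for ann in annotations:
        ab = {
            gid: universe_ab[idx]
            for idx, gid in book.gene_ids[ann.name].items()
        }
        cm, tl = generate_counts(cfg, ann, abundance=ab)
        counts[ann.name] = cm
        true_expr[ann.name] = tl
        tabs, tmap = generate_truth_tables(cfg, tl, rng=cfg._rng(f"truth:{ann.name}"))
        truth_tables[ann.name] = tabs
        truth_maps[ann.name] = tmap
        if with_fragments:
            fr, pt = generate_fragments(cfg, ann, abundance=ab)
            fragments[ann.name] = fr
            placed_truth[ann.name] = pt

    bundle = SyntheticBundle(
        config=cfg,
        annotations=annotations,
        maps=maps,
        bookkeeping=book,
        counts=counts,
        true_log2_expression=true_expr,
        design=cfg.design(),
        truth_tables=truth_tables,
        truth_maps=truth_maps,
        fragments=fragments,
        placed_truth=placed_truth,
    )
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle to disk: GTFs, maps, counts, truth tables, manifest.

    RT-PCR tables are written on the linear scale (they are re-log2ed on
    read, mirroring how raw RT-PCR data arrive); microarray tables are
    written as log2 values.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    cfg = bundle.config
    for ann in bundle.annotations:
        write_gtf(ann, os.path.join(outdir, f"{ann.name}.gtf"))
        bundle.counts[ann.name].write_tsv(os.path.join(outdir, f"{ann.name}.counts.tsv"))
        df = bundle.true_log2_expression[ann.name]
        df.round(10).to_csv(os.path.join(outdir, f"{ann.name}.true_log2.tsv"), sep="\t")
        tabs = bundle.truth_tables[ann.name]
        rt = np.exp2(tabs["rtpcr"].data).round(10)
        rt.index.name = "gene_id"
        rt.to_csv(os.path.join(outdir, f"{ann.name}.truth_rtpcr.tsv"), sep="\t")
        ma = tabs["microarray"].data.round(10)
        ma.to_csv(os.path.join(outdir, f"{ann.name}.truth_microarray.tsv"), sep="\t")
        bundle.truth_maps[ann.name].write_tsv(os.path.join(outdir, f"{ann.name}.truth_map.tsv"))
    for (ni, nj), idmap in bundle.maps.items():
        idmap.write_tsv(os.path.join(outdir, f"map.{ni}.{nj}.tsv"))
    if bundle.fragments:
        for name, per_lib in bundle.fragments.items():
            for lib, frags in per_lib.items():
                write_fragments_bed(frags, os.path.join(outdir, f"{name}.{lib}.bed"))
    manifest = {"seed": cfg.seed, "config": asdict(cfg)}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
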