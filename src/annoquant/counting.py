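"""Fragment-to-gene assignment with featureCounts-style semantics.

A *fragment* is a read pair (or single read) with one or more candidate
alignment locations; each candidate is a list of aligned reference blocks.
A fragment is assigned to a gene if any of its blocks overlaps any exon of
that gene by at least one base, unstranded. Fragments overlapping exons of
two or more genes are unassigned (ambiguous); fragments overlapping no exon
are unassigned (no feature).

Multi-mapping fragments are resolved to a single candidate before
assignment: if exactly one candidate overlaps an exon of some gene, that
candidate wins; if several do, the first in canonical order (chromosome
order of the annotation, then leftmost start, then input order) among them;
if none do, the first in canonical order overall.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, GenomicInterval, collapse_exons, effective_length

NO_FEATURE = "__no_feature__"
AMBIGUOUS = "__ambiguous__"

AlignedBlock = GenomicInterval  # aligned reference bases of one read end


@dataclass
class FragmentAlignment:
    """A fragment with >=1 candidate locations (multi-mapping iff >1)."""

    fragment_id: str
    candidates: list[list[AlignedBlock]]
    library_id: str = ""

    def __post_init__(self) -> None:
        if not self.candidates or any(not c for c in self.candidates):
            raise ValueError(f"fragment {self.fragment_id}: empty candidate list")

    @property
    def is_multimapping(self) -> bool:
        return len(self.candidates) > 1


@dataclass
class AssignmentStats:
    """Per-library assignment tallies and multi-mapper classification."""

    assigned: int = 0
    unassigned_no_feature: int = 0
    unassigned_ambiguity: int = 0
    multi_gene: int = 0
    within_one_gene: int = 0
    no_exon: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned_no_feature + self.unassigned_ambiguity

    @property
    def n_multimappers(self) -> int:
        return self.multi_gene + self.within_one_gene + self.no_exon

    def as_dict(self) -> dict[str, int]:
        return {
            "assigned": self.assigned,
            "unassigned_no_feature": self.unassigned_no_feature,
            "unassigned_ambiguity": self.unassigned_ambiguity,
            "multi_gene": self.multi_gene,
            "within_one_gene": self.within_one_gene,
            "no_exon": self.no_exon,
        }


@dataclass
class CountMatrix:
    """Genes x libraries integer counts with per-library assigned totals."""

    gene_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray
    stats: dict[str, AssignmentStats] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ValueError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> np.ndarray:
        """Total assigned fragments per library (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.library_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, lengths: dict[str, int] | None = None) -> "CountMatrix":
        return cls(
            gene_ids=list(df.index),
            library_ids=list(df.columns),
            counts=df.to_numpy(),
            lengths=lengths or {},
        )

    def write_tsv(self, path) -> None:
        """featureCounts-like TSV: gene_id, length, one column per library."""
        with open(path, "w") as fh:
            fh.write("gene_id\tlength\t" + "\t".join(self.library_ids) + "\n")
            for i, gid in enumerate(self.gene_ids):
                length = self.lengths.get(gid, 0)
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"{gid}\t{length}\t{row}\n")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = df["length"].astype(int).to_dict()
        counts = df.drop(columns=["length"])
        return cls(
            gene_ids=list(counts.index),
            library_ids=list(counts.columns),
            counts=counts.to_numpy().astype(np.int64),
            lengths=lengths,
        )

    def write_stats_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = [
                "library_id",
                "assigned",
                "unassigned_no_feature",
                "unassigned_ambiguity",
                "multi_gene",
                "within_one_gene",
                "no_exon",
            ]
            fh.write("\t".join(cols) + "\n")
            for lib in self.library_ids:
                st = self.stats.get(lib, AssignmentStats())
                d = st.as_dict()
                fh.write("\t".join([lib] + [str(d[c]) for c in cols[1:]]) + "\n")


# ---------------------------------------------------------------------------
# Exon interval index


class GeneIndex:
    """Interval index over the collapsed exons of an annotation."""

    def __init__(self, annotation: AnnotationSet):
        self.annotation = annotation
        self.chrom_rank = {c: i for i, c in enumerate(annotation.chrom_order)}
        self.trees: dict[str, IntervalTree] = {}
        self.lengths: dict[str, int] = {}
        for gene in annotation:
            collapsed = collapse_exons(gene)
            self.lengths[gene.gene_id] = effective_length(collapsed)
            for ex in collapsed.exons:
                self.trees.setdefault(ex.chrom, IntervalTree()).addi(
                    ex.start, ex.end, gene.gene_id
                )

    def genes_hit(self, blocks: Iterable[AlignedBlock]) -> set[str]:
        hits: set[str] = set()
        for block in blocks:
            tree = self.trees.get(block.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(block.start, block.end):
                hits.add(iv.data)
        return hits


def assign_fragment(blocks: list[AlignedBlock], index: GeneIndex) -> str:
    """Assign one candidate location to a gene, NO_FEATURE or AMBIGUOUS."""
    hits = index.genes_hit(blocks)
    if not hits:
        return NO_FEATURE
    if len(hits) > 1:
        return AMBIGUOUS
    return next(iter(hits))


def _candidate_sort_key(index: GeneIndex, blocks: list[AlignedBlock], order: int):
    first = min(blocks, key=lambda b: (index.chrom_rank.get(b.chrom, len(index.chrom_rank)), b.start))
    return (index.chrom_rank.get(first.chrom, len(index.chrom_rank)), first.start, order)


def resolve_multimapper(fragment: FragmentAlignment, index: GeneIndex) -> int:
    """Pick the final candidate for a multi-mapping fragment.

    Exactly one exon-overlapping candidate wins outright; among several, the
    first in canonical order; with none, the first in canonical order of all
    candidates.
    """
    if len(fragment.candidates) < 2:
        return 0
    exonic = [i for i, c in enumerate(fragment.candidates) if index.genes_hit(c)]
    pool = exonic if exonic else range(len(fragment.candidates))
    if len(pool) == 1:
        return pool[0] if exonic else 0
    return min(pool, key=lambda i: _candidate_sort_key(index, fragment.candidates[i], i))


def classify_multimapper(fragment: FragmentAlignment, index: GeneIndex) -> str:
    """Classify a multi-mapper by the genes its candidates collectively hit.

    'multi_gene' if the candidates overlap exons of two or more genes,
    'within_one_gene' if every exon overlap hits the same single gene,
    'no_exon' if no candidate overlaps any exon.
    """
    genes: set[str] = set()
    for cand in fragment.candidates:
        genes |= index.genes_hit(cand)
    if not genes:
        return "no_exon"
    return "within_one_gene" if len(genes) == 1 else "multi_gene"


def count_library(
    fragments: Iterable[FragmentAlignment],
    annotation: AnnotationSet,
    index: GeneIndex | None = None,
    library_id: str = "",
) -> tuple[pd.Series, AssignmentStats]:
    """Count fragments to genes for one library.

    Multi-mappers are first resolved to one candidate, then every fragment is
    assigned to exactly one gene or failure category; the tallies are
    conserved (assigned + no_feature + ambiguity = fragments processed).
    """
    if index is None:
        index = GeneIndex(annotation)
    counts = {gid: 0 for gid in annotation.genes}
    stats = AssignmentStats()
    for frag in fragments:
        if frag.is_multimapping:
            cls = classify_multimapper(frag, index)
            setattr(stats, cls, getattr(stats, cls) + 1)
            blocks = frag.candidates[resolve_multimapper(frag, index)]
        else:
            blocks = frag.candidates[0]
        result = assign_fragment(blocks, index)
        if result == NO_FEATURE:
            stats.unassigned_no_feature += 1
        elif result == AMBIGUOUS:
            stats.unassigned_ambiguity += 1
        else:
            counts[result] += 1
            stats.assigned += 1
    return pd.Series(counts, name=library_id or "counts"), stats


def count_libraries(
    per_library_fragments: dict[str, Iterable[FragmentAlignment]],
    annotation: AnnotationSet,
) -> CountMatrix:
    """Count several libraries against one annotation into a CountMatrix."""
    index = GeneIndex(annotation)
    columns = {}
    stats = {}
    for lib, frags in per_library_fragments.items():
        col, st = count_library(frags, annotation, index=index, library_id=lib)
        columns[lib] = col
        stats[lib] = st
    df = pd.DataFrame(columns)
    cm = CountMatrix(
        gene_ids=list(df.index),
        library_ids=list(df.columns),
        counts=df.to_numpy(),
        stats=stats,
        lengths=dict(index.lengths),
    )
    return cm


def assigned_fraction_by_biotype(counts: CountMatrix, annotation: AnnotationSet) -> pd.DataFrame:
    """Per-library fraction of assigned fragments landing in each biotype.

    Fractions are over assigned fragments and sum to 1 per library; a library
    with zero assigned fragments gets all-zero fractions (with a warning).
    """
    import logging

    biotypes = sorted(
        {(annotation.genes[g].biotype or "unannotated") for g in counts.gene_ids if g in annotation}
    )
    bt_of = {
        g: (annotation.genes[g].biotype or "unannotated")
        for g in counts.gene_ids
        if g in annotation
    }
    out = pd.DataFrame(0.0, index=biotypes, columns=counts.library_ids)
    df = counts.to_dataframe()
    totals = df.sum(axis=0)
    grouped = df.groupby(df.index.map(bt_of)).sum()
    for lib in counts.library_ids:
        if totals[lib] == 0:
            logging.getLogger(__name__).warning("library %s has zero assigned fragments", lib)
            continue
        out[lib] = grouped[lib].reindex(biotypes).fillna(0) / totals[lib]
    return out


# ---------------------------------------------------------------------------
# Fragment readers


def _open_maybe_gzip(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    return gzip.open(path, "rt") if magic == b"\x1f\x8b" else open(path, "rt")


def read_fragments_bed(path, library_id: str = "") -> Iterator[FragmentAlignment]:
    """Read fragments from BED3+ (optional 4th name column).

    Consecutive-or-not lines sharing a name are candidates of one
    multi-mapping fragment; unnamed lines are independent single-candidate
    fragments. Each candidate is a single block.
    """
    by_name: dict[str, list[list[AlignedBlock]]] = {}
    order: list[str] = []
    anon = 0
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: BED needs >=3 columns")
            try:
                block = AlignedBlock(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if len(fields) >= 4 and fields[3] not in (".", ""):
                name = fields[3]
            else:
                anon += 1
                name = f"__anon_{anon}"
            if name not in by_name:
                by_name[name] = []
                order.append(name)
            by_name[name].append([block])
    for name in order:
        yield FragmentAlignment(fragment_id=name, candidates=by_name[name], library_id=library_id)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_blocks(chrom: str, pos0: int, cigar: str) -> list[AlignedBlock]:
    """Reference blocks (M/=/X runs) of an alignment; N and D split blocks.

    *pos0* is the 0-based leftmost reference coordinate. Insertions and
    soft/hard clips consume no reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or sum(len(n) + 1 for n, _ in ops) != len(cigar):
        raise ValueError(f"cannot parse CIGAR {cigar!r}")
    blocks: list[AlignedBlock] = []
    ref = pos0
    run_start = None
    for length_s, op in ops:
        length = int(length_s)
        if op in "M=X":
            if run_start is None:
                run_start = ref
            ref += length
        elif op in "DN":
            if run_start is not None:
                blocks.append(AlignedBlock(chrom, run_start, ref))
                run_start = None
            ref += length
        # I, S, H, P consume no reference
    if run_start is not None:
        blocks.append(AlignedBlock(chrom, run_start, ref))
    return blocks


def read_fragments_sam(path, library_id: str = "") -> Iterator[FragmentAlignment]:
    """Read fragments from a minimal SAM subset.

    Uses QNAME, FLAG, RNAME, POS and CIGAR only. Records sharing a QNAME are
    grouped into one fragment: primary mates contribute their blocks to the
    primary candidate; each secondary record (flag 0x100) opens or extends a
    secondary candidate, paired mate-wise in file order. Unmapped records
    (flag 0x4 or RNAME '*') are skipped.
    """
    frags: dict[str, dict] = {}
    order: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: SAM record with <6 fields")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            flag = int(flag_s)
            if flag & 0x4 or rname == "*" or cigar == "*":
                continue
            try:
                blocks = cigar_blocks(rname, int(pos_s) - 1, cigar)
            except ValueError as exc:
                raise ValueError(f"{path}: record {qname}: {exc}") from exc
            if qname not in frags:
                frags[qname] = {"primary": [], "secondary": []}
                order.append(qname)
            if flag & 0x100:
                frags[qname]["secondary"].append(blocks)
            else:
                frags[qname]["primary"].extend(blocks)
    for qname in order:
        rec = frags[qname]
        candidates: list[list[AlignedBlock]] = []
        if rec["primary"]:
            candidates.append(rec["primary"])
        candidates.extend(rec["secondary"])
        if candidates:
            yield FragmentAlignment(fragment_id=qname, candidates=candidates, library_id=library_id)
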