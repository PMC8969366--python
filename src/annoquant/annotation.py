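"""Gene models parsed from GTF annotations.

Coordinates are stored 0-based half-open internally; GTF files on disk are
1-based inclusive. The unit of quantification is the *gene*: a set of exon
intervals (possibly from many transcripts) with a biotype and identifiers.
The effective length of a gene is the number of unique genomic bases covered
by its exons; the transcriptome size of an annotation is the sum of effective
gene lengths over all its genes (bases shared between overlapping genes count
once per gene).
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


class DialectError(ValueError):
    """Raised for an unknown GTF dialect name."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome; strand '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene: identifiers, biotype and a non-empty set of exon intervals."""

    gene_id: str
    exons: list[GenomicInterval]
    symbol: str | None = None
    biotype: str | None = None
    secondary_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for ex in self.exons:
            seen.setdefault(ex.chrom, None)
        return list(seen)

    @property
    def strand(self) -> str:
        strands = {ex.strand for ex in self.exons}
        return strands.pop() if len(strands) == 1 else "."


@dataclass
class AnnotationSet:
    """A named collection of gene models keyed by gene_id.

    ``chrom_order`` lists chromosomes in first-encountered order and defines
    the canonical location order used by multi-mapper resolution downstream.
    """

    name: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_order: list[str] = field(default_factory=list)
    n_excluded_no_exon: int = 0

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id} in {self.name}")
        self.genes[gene.gene_id] = gene
        for chrom in gene.chroms:
            if chrom not in self._chrom_set:
                self._chrom_set.add(chrom)
                self.chrom_order.append(chrom)

    def __post_init__(self) -> None:
        self._chrom_set = set(self.chrom_order)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


# ---------------------------------------------------------------------------
# GTF parsing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_DIALECTS = {"ensembl", "refseq", "generic"}
_BIOTYPE_KEYS = ("gene_biotype", "gene_type")


def _parse_attributes(attr_field: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for key, value in _ATTR_RE.findall(attr_field):
        out.setdefault(key, []).append(value)
    return out


def _open_text(path):
    # gzip-transparent open
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path, dialect: str = "generic") -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` feature rows define quantification structure; ``gene`` rows
    may seed symbol/biotype metadata. Genes without any exon record are
    excluded and counted in ``n_excluded_no_exon``. The RefSeq dialect
    additionally parses ``db_xref "GeneID:<n>"`` into ``secondary_ids``.
    """
    if dialect not in _DIALECTS:
        raise DialectError(f"unknown GTF dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")

    import os

    name = str(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    chrom_order: list[str] = []
    chrom_seen: set[str] = set()
    genes_seen: dict[str, None] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{name}, line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{name}, line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"{name}, line {lineno}: invalid coordinates {start1}..{end1}")
            if feature not in ("exon", "gene"):
                continue
            attrs = _parse_attributes(attrs_s)
            gene_ids = attrs.get("gene_id")
            if not gene_ids:
                raise GtfParseError(f"{name}, line {lineno}: missing gene_id attribute")
            gene_id = gene_ids[0]
            genes_seen.setdefault(gene_id, None)
            rec = meta.setdefault(gene_id, {"symbol": None, "biotype": None, "secondary_ids": {}})
            if rec["symbol"] is None:
                for key in ("gene_name", "gene"):
                    if key in attrs:
                        rec["symbol"] = attrs[key][0]
                        break
            if rec["biotype"] is None:
                for key in _BIOTYPE_KEYS:
                    if key in attrs:
                        rec["biotype"] = attrs[key][0]
                        break
            if dialect == "refseq":
                for xref in attrs.get("db_xref", []):
                    if xref.startswith("GeneID:"):
                        rec["secondary_ids"].setdefault("GeneID", xref.split(":", 1)[1])
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                strand = "."
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons.setdefault(gene_id, []).append(interval)
            if chrom not in chrom_seen:
                chrom_seen.add(chrom)
                chrom_order.append(chrom)

    annotation = AnnotationSet(name=name, chrom_order=chrom_order)
    n_excluded = 0
    for gene_id in genes_seen:
        if gene_id not in exons:
            n_excluded += 1
            continue
        rec = meta[gene_id]
        annotation.add(
            GeneModel(
                gene_id=gene_id,
                exons=sorted(exons[gene_id]),
                symbol=rec["symbol"],
                biotype=rec["biotype"],
                secondary_ids=rec["secondary_ids"],
            )
        )
    annotation.n_excluded_no_exon = n_excluded
    if not annotation.genes:
        logger.warning("no genes with exons parsed from %s", name)
    if n_excluded:
        logger.info("%s: excluded %d genes without exon records", name, n_excluded)
    return annotation


# ---------------------------------------------------------------------------
# Per-gene and per-annotation statistics


def collapse_exons(gene: GeneModel) -> GeneModel:
    """Return a copy of *gene* with overlapping or adjacent exons merged.

    The merged representation is canonical (pairwise-disjoint, sorted) and
    preserves effective length. Exons on different chromosomes are merged
    independently.
    """
    by_chrom: dict[tuple[str, str], list[GenomicInterval]] = {}
    for ex in gene.exons:
        by_chrom.setdefault((ex.chrom, ex.strand), []).append(ex)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return GeneModel(
        gene_id=gene.gene_id,
        exons=sorted(merged),
        symbol=gene.symbol,
        biotype=gene.biotype,
        secondary_ids=dict(gene.secondary_ids),
    )


def effective_length(gene: GeneModel) -> int:
    """Number of unique bases in the union of the gene's exons.

    Chromosomes contribute independent unions that are summed; strand is
    ignored.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ex in gene.exons:
        by_chrom.setdefault(ex.chrom, []).append(ex)
    total = 0
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
        total += cur_end - cur_start
    return total


def transcriptome_size(annotation: AnnotationSet) -> int:
    """Sum of effective gene lengths over all genes in the annotation.

    Bases shared between overlapping genes are counted once per gene.
    """
    return sum(effective_length(g) for g in annotation)


def find_overlapping_gene_pairs(annotation: AnnotationSet) -> list[tuple[str, str]]:
    """Every unordered pair of distinct genes sharing >=1 exonic base.

    Strand is ignored. Uses a sweep over per-chromosome sorted exon
    endpoints; complexity O(E log E + pairs).
    """
    events: dict[str, list[tuple[int, int, str]]] = {}
    for gene in annotation:
        for ex in collapse_exons(gene).exons:
            events.setdefault(ex.chrom, []).append((ex.start, ex.end, gene.gene_id))
    pairs: set[tuple[str, str]] = set()
    for ivs in events.values():
        ivs.sort()
        active: list[tuple[int, str]] = []  # (end, gene_id)
        for start, end, gid in ivs:
            active = [(e, g) for e, g in active if e > start]
            for _e, other in active:
                if other != gid:
                    pairs.add((min(gid, other), max(gid, other)))
            active.append((end, gid))
    return sorted(pairs)


def biotype_summary(annotation: AnnotationSet) -> dict[str, int]:
    """Gene counts per biotype; genes without a biotype count as 'unannotated'."""
    counts: dict[str, int] = {}
    for gene in annotation:
        key = gene.biotype if gene.biotype else "unannotated"
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Writers


def write_gene_table(annotation: AnnotationSet, path) -> None:
    """Write a TSV gene table (one row per gene, 0-based half-open lengths)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tbiotype\tchrom\tstrand\tn_exons\teffective_length\n")
        for gene_id in sorted(annotation.genes):
            gene = annotation.genes[gene_id]
            collapsed = collapse_exons(gene)
            fh.write(
                "\t".join(
                    [
                        gene.gene_id,
                        gene.symbol or "",
                        gene.biotype or "unannotated",
                        ",".join(gene.chroms),
                        gene.strand,
                        str(len(collapsed.exons)),
                        str(effective_length(gene)),
                    ]
                )
                + "\n"
            )


def write_annotation_summary(annotation: AnnotationSet, path) -> None:
    """Write a JSON summary: gene count, transcriptome size, biotype table."""
    summary = {
        "name": annotation.name,
        "n_genes": len(annotation),
        "n_excluded_no_exon": annotation.n_excluded_no_exon,
        "transcriptome_size": transcriptome_size(annotation),
        "biotypes": biotype_summary(annotation),
        "coordinate_convention": "0-based half-open",
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write the annotation back to GTF (1-based inclusive exon rows)."""
    with open(path, "w") as fh:
        for gene_id in sorted(annotation.genes):
            gene = annotation.genes[gene_id]
            attrs = f'gene_id "{gene.gene_id}";'
            if gene.symbol:
                attrs += f' gene_name "{gene.symbol}";'
            if gene.biotype:
                attrs += f' gene_biotype "{gene.biotype}";'
            for ns, val in sorted(gene.secondary_ids.items()):
                attrs += f' db_xref "{ns}:{val}";'
            for ex in sorted(gene.exons):
                strand = ex.strand if ex.strand in ("+", "-") else "+"
                fh.write(
                    f"{ex.chrom}\tannoquant\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t{attrs}\n"
                )
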