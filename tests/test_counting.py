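"""featureCounts-style assignment: readers, decision rules, oracle equivalence."""

import itertools

import numpy as np
import pytest

from annoquant.annotation import GenomicInterval, collapse_exons
from annoquant.counting import (
    AMBIGUOUS,
    NO_FEATURE,
    AlignedBlock,
    AssignmentStats,
    FragmentAlignment,
    GeneIndex,
    assign_fragment,
    assigned_fraction_by_biotype,
    cigar_blocks,
    classify_multimapper,
    count_libraries,
    count_library,
    read_fragments_bed,
    read_fragments_sam,
    resolve_multimapper,
)
from conftest import make_annotation, make_gene, random_annotation


# ---------------------------------------------------------------------------
# Independent brute-force assigner (plain loops over all genes and exons)


def brute_genes_hit(blocks, annotation):
    hits = set()
    for gene in annotation:
        for ex in gene.exons:
            for b in blocks:
                if b.chrom == ex.chrom and b.start < ex.end and ex.start < b.end:
                    hits.add(gene.gene_id)
    return hits


def brute_count_library(fragments, annotation):
    chrom_rank = {c: i for i, c in enumerate(annotation.chrom_order)}
    counts = {g: 0 for g in annotation.genes}
    stats = AssignmentStats()
    for frag in fragments:
        if len(frag.candidates) > 1:
            all_genes = set()
            for cand in frag.candidates:
                all_genes |= brute_genes_hit(cand, annotation)
            if not all_genes:
                stats.no_exon += 1
            elif len(all_genes) == 1:
                stats.within_one_gene += 1
            else:
                stats.multi_gene += 1
            exonic = [i for i, c in enumerate(frag.candidates) if brute_genes_hit(c, annotation)]
            pool = exonic if exonic else list(range(len(frag.candidates)))

            def key(i):
                first = min(
                    frag.candidates[i],
                    key=lambda b: (chrom_rank.get(b.chrom, len(chrom_rank)), b.start),
                )
                return (chrom_rank.get(first.chrom, len(chrom_rank)), first.start, i)

            blocks = frag.candidates[min(pool, key=key)]
        else:
            blocks = frag.candidates[0]
        hit = brute_genes_hit(blocks, annotation)
        if not hit:
            stats.unassigned_no_feature += 1
        elif len(hit) > 1:
            stats.unassigned_ambiguity += 1
        else:
            counts[hit.pop()] += 1
            stats.assigned += 1
    return counts, stats


def random_fragments(rng, annotation, n=300, span=50_000):
    frags = []
    for i in range(n):
        n_cand = int(rng.choice([1, 1, 1, 2, 3]))
        cands = []
        for _ in range(n_cand):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, span))
            cands.append([AlignedBlock(chrom, start, start + int(rng.integers(50, 300)))])
        frags.append(FragmentAlignment(fragment_id=f"f{i}", candidates=cands))
    return frags


# ---------------------------------------------------------------------------


class TestAssignFragment:
    def test_block_inside_exon(self, two_gene_annotation):
        index = GeneIndex(two_gene_annotation)
        assert assign_fragment([AlignedBlock("chr1", 110, 160)], index) == "gene1"

    def test_block_spanning_two_genes_is_ambiguous(self):
        ann = make_annotation(
            "t", [make_gene("a", [(0, 100)]), make_gene("b", [(80, 200)])]
        )
        index = GeneIndex(ann)
        assert assign_fragment([AlignedBlock("chr1", 70, 120)], index) == AMBIGUOUS

    def test_intronic_block_is_no_feature(self, two_gene_annotation):
        index = GeneIndex(two_gene_annotation)
        assert assign_fragment([AlignedBlock("chr1", 250, 350)], index) == NO_FEATURE

    def test_single_base_overlap_counts(self, two_gene_annotation):
        index = GeneIndex(two_gene_annotation)
        assert assign_fragment([AlignedBlock("chr1", 199, 260)], index) == "gene1"


class TestMultimapperDecisionTable:
    """Exhaustive enumeration of candidate kinds x 1-3 candidates."""

    KINDS = ("exonic_g1", "exonic_g2", "intronic", "intergenic")

    @pytest.fixture(autouse=True)
    def _setup(self, two_gene_annotation):
        self.ann = two_gene_annotation
        self.index = GeneIndex(self.ann)

    def block(self, kind, slot):
        # distinct start per slot so canonical ordering is exercised
        starts = {
            "exonic_g1": 110,
            "exonic_g2": 1010,
            "intronic": 210,
            "intergenic": 5000,
        }
        s = starts[kind] + 7 * slot
        return AlignedBlock("chr1", s, s + 40)

    def gene_of(self, kind):
        return {"exonic_g1": "gene1", "exonic_g2": "gene2"}.get(kind)

    def test_exhaustive_configurations(self):
        for n_cand in (2, 3):
            for kinds in itertools.product(self.KINDS, repeat=n_cand):
                cands = [[self.block(k, i)] for i, k in enumerate(kinds)]
                frag = FragmentAlignment(fragment_id="f", candidates=cands)
                genes = {self.gene_of(k) for k in kinds} - {None}
                expected_class = (
                    "no_exon" if not genes
                    else "within_one_gene" if len(genes) == 1
                    else "multi_gene"
                )
                assert classify_multimapper(frag, self.index) == expected_class, kinds

                exonic_idx = [i for i, k in enumerate(kinds) if self.gene_of(k)]
                if len(exonic_idx) == 1:
                    expected_resolve = exonic_idx[0]
                else:
                    pool = exonic_idx if exonic_idx else range(n_cand)
                    expected_resolve = min(pool, key=lambda i: cands[i][0].start)
                assert resolve_multimapper(frag, self.index) == expected_resolve, kinds

    def test_single_candidate_assignments(self):
        for kind in self.KINDS:
            frag = FragmentAlignment(fragment_id="f", candidates=[[self.block(kind, 0)]])
            result = assign_fragment(frag.candidates[0], self.index)
            gene = self.gene_of(kind)
            assert result == (gene if gene else NO_FEATURE)

    def test_resolution_respects_chrom_order(self):
        # a candidate on a later chromosome loses to an earlier one even
        # with a smaller start coordinate
        ann = make_annotation(
            "t",
            [make_gene("a", [(500, 600)], chrom="chr1"), make_gene("b", [(0, 100)], chrom="chr2")],
            chrom_order=("chr1", "chr2"),
        )
        index = GeneIndex(ann)
        frag = FragmentAlignment(
            fragment_id="f",
            candidates=[[AlignedBlock("chr2", 10, 60)], [AlignedBlock("chr1", 510, 560)]],
        )
        assert resolve_multimapper(frag, index) == 1


class TestCountLibrary:
    def test_all_in_one_gene(self, two_gene_annotation):
        frags = [
            FragmentAlignment(fragment_id=f"f{i}", candidates=[[AlignedBlock("chr1", 110, 160)]])
            for i in range(10)
        ]
        col, stats = count_library(frags, two_gene_annotation)
        assert col["gene1"] == 10 and stats.assigned == 10
        assert stats.total == 10

    def test_empty_stream(self, two_gene_annotation):
        col, stats = count_library([], two_gene_annotation)
        assert col.sum() == 0 and stats.total == 0

    def test_conservation_and_oracle_equivalence(self, rng):
        for trial in range(6):
            ann = random_annotation(rng, n_genes=40, span=20_000)
            frags = random_fragments(rng, ann, n=300, span=25_000)
            col, stats = count_library(frags, ann)
            bcounts, bstats = brute_count_library(frags, ann)
            assert col.to_dict() == bcounts
            assert stats.as_dict() == bstats.as_dict()
            assert stats.total == len(frags)
            assert stats.n_multimappers == sum(1 for f in frags if f.is_multimapping)

    def test_order_invariance(self, rng):
        ann = random_annotation(rng, n_genes=30)
        frags = random_fragments(rng, ann, n=200)
        col1, st1 = count_library(frags, ann)
        col2, st2 = count_library(list(reversed(frags)), ann)
        assert col1.to_dict() == col2.to_dict()
        assert st1.as_dict() == st2.as_dict()


class TestBiotypeFractions:
    def test_all_protein_coding(self, two_gene_annotation):
        frags = {
            "lib1": [
                FragmentAlignment(fragment_id="f", candidates=[[AlignedBlock("chr1", 110, 160)]])
            ]
        }
        cm = count_libraries(frags, two_gene_annotation)
        table = assigned_fraction_by_biotype(cm, two_gene_annotation)
        assert table.loc["protein_coding", "lib1"] == 1.0
        assert table["lib1"].sum() == pytest.approx(1.0)

    def test_zero_assigned_gives_zeros(self, two_gene_annotation):
        frags = {"lib1": []}
        cm = count_libraries(frags, two_gene_annotation)
        table = assigned_fraction_by_biotype(cm, two_gene_annotation)
        assert (table["lib1"] == 0).all()
        assert np.isfinite(table.to_numpy()).all()


class TestReaders:
    def test_bed_unnamed_lines(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chr1\t0\t50\nchr1\t100\t150\nchr2\t5\t25\n")
        frags = list(read_fragments_bed(p))
        assert len(frags) == 3
        assert all(len(f.candidates) == 1 for f in frags)

    def test_bed_named_multimapper(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chr1\t0\t50\tf1\nchr2\t100\t150\tf1\n")
        frags = list(read_fragments_bed(p))
        assert len(frags) == 1 and len(frags[0].candidates) == 2

    def test_bed_empty(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("")
        assert list(read_fragments_bed(p)) == []

    def test_bed_malformed(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chr1\t10\n")
        with pytest.raises(ValueError):
            list(read_fragments_bed(p))

    def test_cigar_spliced_blocks(self):
        # 50M200N50M starting at 0-based 100: blocks [100,150) and [350,400)
        blocks = cigar_blocks("chr1", 100, "50M200N50M")
        assert [(b.start, b.end) for b in blocks] == [(100, 150), (350, 400)]

    def test_cigar_insertion_and_clip(self):
        blocks = cigar_blocks("chr1", 0, "10S30M5I30M")
        assert [(b.start, b.end) for b in blocks] == [(0, 60)]

    def test_cigar_reference_walk_oracle(self, rng):
        # walk the reference base by base, independently of the parser
        for _ in range(20):
            ops = []
            for _ in range(int(rng.integers(1, 6))):
                op = str(rng.choice(list("MIDNS")))
                ops.append((int(rng.integers(1, 50)), op))
            if not any(op == "M" for _, op in ops):
                ops.append((10, "M"))
            cigar = "".join(f"{n}{op}" for n, op in ops)
            pos = 1000
            covered = []
            ref = pos
            for n, op in ops:
                if op == "M":
                    covered.extend(range(ref, ref + n))
                    ref += n
                elif op in "DN":
                    ref += n
            blocks = cigar_blocks("chr1", pos, cigar)
            from_blocks = [b for blk in blocks for b in range(blk.start, blk.end)]
            assert from_blocks == covered

    def test_sam_proper_pair_one_candidate(self, tmp_path):
        p = tmp_path / "f.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
            "r1\t99\tchr1\t101\t60\t100M\t=\t301\t300\t*\t*\n"
            "r1\t147\tchr1\t301\t60\t100M\t=\t101\t-300\t*\t*\n"
        )
        frags = list(read_fragments_sam(p))
        assert len(frags) == 1
        assert len(frags[0].candidates) == 1
        assert [(b.start, b.end) for b in frags[0].candidates[0]] == [(100, 200), (300, 400)]

    def test_sam_secondary_extra_candidate(self, tmp_path):
        p = tmp_path / "f.sam"
        p.write_text(
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*\n"
            "r1\t256\tchr2\t501\t0\t50M\t*\t0\t0\t*\t*\n"
        )
        frags = list(read_fragments_sam(p))
        assert len(frags) == 1 and len(frags[0].candidates) == 2

    def test_sam_unmapped_skipped(self, tmp_path):
        p = tmp_path / "f.sam"
        p.write_text("r1\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        assert list(read_fragments_sam(p)) == []

    def test_sam_matches_pysam(self, tmp_path):
        """Dual-route check of the minimal SAM reader against pysam."""
        pysam = pytest.importorskip("pysam")
        p = tmp_path / "f.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
            "r1\t0\tchr1\t101\t60\t30M10N30M\t*\t0\t0\t*\t*\n"
            "r2\t0\tchr1\t2001\t60\t25M5D25M\t*\t0\t0\t*\t*\n"
        )
        mine = {f.fragment_id: f.candidates[0] for f in read_fragments_sam(p)}
        with pysam.AlignmentFile(str(p), "r") as sam:
            for rec in sam:
                expected = [(s, e) for s, e in rec.get_blocks()]
                got = [(b.start, b.end) for b in mine[rec.query_name]]
                # pysam merges D-adjacent blocks in get_blocks for M runs;
                # compare covered reference bases instead of raw blocks
                cover = lambda ivs: {b for s, e in ivs for b in range(s, e)}
                assert cover(got) == cover(expected)
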