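import numpy as np
import pytest

from annoquant.annotation import AnnotationSet, GeneModel, GenomicInterval


def make_gene(gene_id, exons, biotype="protein_coding", chrom="chr1", strand="+"):
    return GeneModel(
        gene_id=gene_id,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
    )


def make_annotation(name, genes, chrom_order=("chr1",)):
    ann = AnnotationSet(name=name, chrom_order=list(chrom_order))
    for g in genes:
        ann.add(g)
    return ann


@pytest.fixture
def two_gene_annotation():
    """gene1: exons [100,200)+[400,500); gene2: exon [1000,1100)."""
    return make_annotation(
        "toy",
        [
            make_gene("gene1", [(100, 200), (400, 500)]),
            make_gene("gene2", [(1000, 1100)], biotype="lncRNA"),
        ],
    )


def random_annotation(rng, n_genes=50, n_chroms=2, span=50_000):
    """Random annotation with arbitrary (possibly overlapping) exons."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        n_exons = int(rng.integers(1, 5))
        exons = []
        for _ in range(n_exons):
            start = int(rng.integers(0, span))
            length = int(rng.integers(1, 400))
            exons.append((start, start + length))
        genes.append(make_gene(f"g{i}", exons, chrom=chrom))
    return make_annotation(
        "random", genes, chrom_order=[f"chr{c}" for c in range(1, n_chroms + 1)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
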