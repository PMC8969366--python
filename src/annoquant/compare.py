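"""Cross-annotation gene matching and concordance statistics.

Genes are matched across annotations purely by identifier, through explicit
two-column mapping tables (no coordinate matching). Comparisons restrict to
genes with a one-to-one mapping between the two annotations; everything else
is reported as unmatched or dropped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, effective_length

logger = logging.getLogger(__name__)


@dataclass
class IdentifierMap:
    """Pairs of (source_id, target_id); may be many-to-many as loaded."""

    pairs: list[tuple[str, str]]
    namespaces: tuple[str, str] = ("A", "B")

    @classmethod
    def read_tsv(cls, path) -> "IdentifierMap":
        """Read a two-column TSV; a header row names the namespaces."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: mapping table needs two id columns")
        a, b = df.columns[:2]
        pairs = list(zip(df[a].astype(str), df[b].astype(str)))
        return cls(pairs=pairs, namespaces=(a, b))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.namespaces[0]}\t{self.namespaces[1]}\n")
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")

    def reversed(self) -> "IdentifierMap":
        return IdentifierMap(
            pairs=[(b, a) for a, b in self.pairs],
            namespaces=(self.namespaces[1], self.namespaces[0]),
        )


@dataclass
class GeneMatchResult:
    matched: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    dropped_multimap: list[str] = field(default_factory=list)


def match_genes(a: AnnotationSet, b: AnnotationSet, idmap: IdentifierMap) -> GeneMatchResult:
    """One-to-one gene matching between two annotations.

    The map is first restricted to pairs whose ids exist in their respective
    annotations; pairs that are then 1:1 in both directions form ``matched``.
    Genes involved in residual many-to-many mappings go to
    ``dropped_multimap``; genes with no (restricted) mapping at all are
    unmatched.
    """
    present = [(x, y) for x, y in dict.fromkeys(idmap.pairs) if x in a and y in b]
    deg_a: dict[str, int] = {}
    deg_b: dict[str, int] = {}
    for x, y in present:
        deg_a[x] = deg_a.get(x, 0) + 1
        deg_b[y] = deg_b.get(y, 0) + 1
    matched = [(x, y) for x, y in present if deg_a[x] == 1 and deg_b[y] == 1]
    dropped: set[str] = set()
    for x, y in present:
        if deg_a[x] > 1 or deg_b[y] > 1:
            dropped.add(x)
            dropped.add(y)
    matched_ids = {x for x, _ in matched} | {y for _, y in matched}
    unmatched_a = sorted(g for g in a.genes if g not in matched_ids and g not in dropped)
    unmatched_b = sorted(g for g in b.genes if g not in matched_ids and g not in dropped)
    return GeneMatchResult(
        matched=sorted(matched),
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        dropped_multimap=sorted(dropped),
    )


def overlap_counts(
    annotations: list[AnnotationSet],
    maps: dict[tuple[str, str], IdentifierMap],
    biotype: str | None = None,
) -> dict[frozenset, int]:
    """Venn-region gene-group counts for two or three annotations.

    Keys are frozensets of annotation names; the value for a multi-annotation
    region is the number of matched gene groups in that region (each group
    contributes one gene to every member annotation, so per-annotation region
    counts sum to that annotation's gene count). A gene group spanning all
    three annotations requires the three pairwise 1:1 matches to agree
    transitively; non-transitive triples are demoted to the pairwise region of
    the first consistent pair (in annotation order) and logged.

    With ``biotype`` set, only genes carrying that biotype in their home
    annotation participate.
    """
    if not 2 <= len(annotations) <= 3:
        raise ValueError("overlap_counts expects 2 or 3 annotations")
    names = [ann.name for ann in annotations]
    if len(set(names)) != len(names):
        raise ValueError("annotation names must be distinct")
    ann_by_name = {ann.name: ann for ann in annotations}

    def keep(name: str, gid: str) -> bool:
        if biotype is None:
            return True
        return (ann_by_name[name].genes[gid].biotype or "unannotated") == biotype

    # pairwise 1:1 matches, as dicts keyed both ways
    link: dict[tuple[str, str], dict[str, str]] = {}
    for i, j in itertools.combinations(range(len(annotations)), 2):
        ni, nj = names[i], names[j]
        idmap = maps.get((ni, nj))
        if idmap is None:
            rev = maps.get((nj, ni))
            if rev is None:
                raise ValueError(f"missing identifier map for pair ({ni}, {nj})")
            idmap = rev.reversed()
        res = match_genes(annotations[i], annotations[j], idmap)
        fwd = {x: y for x, y in res.matched if keep(ni, x) and keep(nj, y)}
        link[(ni, nj)] = fwd
        link[(nj, ni)] = {y: x for x, y in fwd.items()}

    regions: dict[frozenset, int] = {}
    assigned: set[tuple[str, str]] = set()  # (annotation name, gene_id)
    n_nontransitive = 0

    if len(annotations) == 3:
        n0, n1, n2 = names
        for g0, g1 in list(link[(n0, n1)].items()):
            g2 = link[(n1, n2)].get(g1)
            g2b = link[(n0, n2)].get(g0)
            if g2 is not None and g2 == g2b:
                regions[frozenset(names)] = regions.get(frozenset(names), 0) + 1
                assigned.update([(n0, g0), (n1, g1), (n2, g2)])
            elif g2 is not None or g2b is not None:
                # chain without a closing edge: demote to the first pairwise
                # region in annotation order; third gene left for its own pair
                n_nontransitive += 1

    for i, j in itertools.combinations(range(len(annotations)), 2):
        ni, nj = names[i], names[j]
        for gi, gj in link[(ni, nj)].items():
            if (ni, gi) in assigned or (nj, gj) in assigned:
                continue
            key = frozenset([ni, nj])
            regions[key] = regions.get(key, 0) + 1
            assigned.add((ni, gi))
            assigned.add((nj, gj))

    for name in names:
        n_unique = sum(
            1
            for gid in ann_by_name[name].genes
            if keep(name, gid) and (name, gid) not in assigned
        )
        if n_unique or biotype is None:
            regions[frozenset([name])] = n_unique

    if n_nontransitive:
        logger.warning(
            "overlap_counts: %d non-transitive identifier triples demoted to pairwise regions",
            n_nontransitive,
        )
    return regions


def common_gene_groups(
    annotations: list[AnnotationSet],
    maps: dict[tuple[str, str], IdentifierMap],
) -> list[tuple[str, ...]]:
    """Gene groups present in *every* annotation under transitive 1:1 matching.

    For two annotations these are the matched pairs; for three, only triples
    whose three pairwise matches close consistently.
    """
    names = [ann.name for ann in annotations]

    def pair_match(i: int, j: int) -> dict[str, str]:
        ni, nj = names[i], names[j]
        idmap = maps.get((ni, nj))
        if idmap is None:
            idmap = maps[(nj, ni)].reversed()
        return dict(match_genes(annotations[i], annotations[j], idmap).matched)

    if len(annotations) == 2:
        return sorted(pair_match(0, 1).items())
    m01 = pair_match(0, 1)
    m12 = pair_match(1, 2)
    m02 = pair_match(0, 2)
    groups = []
    for g0, g1 in m01.items():
        g2 = m12.get(g1)
        if g2 is not None and m02.get(g0) == g2:
            groups.append((g0, g1, g2))
    return sorted(groups)


def biotype_overlap(
    annotations: list[AnnotationSet],
    maps: dict[tuple[str, str], IdentifierMap],
    biotype: str,
) -> dict[frozenset, int]:
    """Venn-region counts restricted to genes of one biotype."""
    table = overlap_counts(annotations, maps, biotype=biotype)
    return {k: v for k, v in table.items() if v > 0}


def length_ratio_distribution(
    match: GeneMatchResult, a: AnnotationSet, b: AnnotationSet
) -> pd.DataFrame:
    """Per-matched-gene log2 ratio of effective lengths (A over B).

    Returns a DataFrame with columns gene_id_a, gene_id_b, length_a, length_b,
    log2_ratio. Summary quantiles are available via ``.describe()`` on the
    ratio column.
    """
    rows = []
    for ga, gb in match.matched:
        la = effective_length(a.genes[ga])
        lb = effective_length(b.genes[gb])
        rows.append((ga, gb, la, lb, math.log2(la / lb)))
    return pd.DataFrame(
        rows, columns=["gene_id_a", "gene_id_b", "length_a", "length_b", "log2_ratio"]
    )


def region_table(regions: dict[frozenset, int], names: list[str]) -> pd.DataFrame:
    """Tidy TSV-friendly view of a Venn-region dict."""
    rows = []
    for key, count in regions.items():
        membership = ["1" if n in key else "0" for n in names]
        rows.append(("&".join(sorted(key)), *membership, count))
    df = pd.DataFrame(rows, columns=["region", *names, "count"])
    return df.sort_values("region", ignore_index=True)
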