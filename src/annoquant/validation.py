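"""Validation of RNA-seq expression against external truth platforms.

Truth tables carry per-sample log2 expression measured on an independent
platform: an RT-PCR-like table (one row per gene) or a microarray-like
table (one or more probes per gene, from which a representative probe — the
one with the highest mean expression across samples — is chosen). Matched
genes are correlated per sample with replicate-averaged RNA-seq log2
expression using Pearson's r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .compare import IdentifierMap
from .normalize import ExpressionMatrix
from .titration import MixtureDesign, replicate_mean_expression

logger = logging.getLogger(__name__)

PLATFORMS = ("rtpcr", "microarray")


@dataclass
class TruthTable:
    """External-platform log2 expression per gene (or probe) per sample."""

    platform: str
    data: pd.DataFrame  # index gene_id (rtpcr) or (gene_id, probe_id); columns samples

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("truth table contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        if isinstance(self.data.index, pd.MultiIndex):
            return list(dict.fromkeys(self.data.index.get_level_values(0)))
        return list(self.data.index)


def read_truth_table(path, platform: str, log2_transform: bool | None = None) -> TruthTable:
    """Read a TSV truth table.

    RT-PCR tables have a ``gene_id`` column; microarray tables have
    ``gene_id`` and ``probe_id`` columns. Remaining columns are samples.
    ``log2_transform`` defaults to True for rtpcr (raw RT-PCR data are
    linear-scale) and False for microarray.
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}")
    if log2_transform is None:
        log2_transform = platform == "rtpcr"
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "probe_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    if platform == "microarray":
        if "probe_id" not in df.columns:
            raise ValueError(f"{path}: microarray table needs a probe_id column")
        df = df.set_index(["gene_id", "probe_id"])
    else:
        if df["gene_id"].duplicated().any():
            dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate gene_id {dup!r} on probe-less platform")
        df = df.set_index("gene_id")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    values = df.astype(float)
    if log2_transform:
        values = np.log2(values)
    return TruthTable(platform=platform, data=values)


def select_representative_probe(probes: pd.DataFrame) -> str:
    """Representative probe for one gene: highest mean over samples.

    Exact ties break to the lexicographically smallest probe_id.
    """
    if probes.empty:
        raise ValueError("no probes given")
    means = probes.mean(axis=1)
    best = means.max()
    winners = sorted(means.index[means == best])
    return winners[0]


def collapse_probes(truth: TruthTable) -> TruthTable:
    """Reduce a microarray table to one representative probe per gene."""
    if truth.platform != "microarray":
        return truth
    rows = {}
    for gene_id, probes in truth.data.groupby(level=0, sort=False):
        probes = probes.droplevel(0)
        rows[gene_id] = probes.loc[select_representative_probe(probes)]
    return TruthTable(platform=truth.platform, data=pd.DataFrame(rows).T[truth.samples])


@dataclass
class MatchToTruth:
    matched: list[tuple[str, str]]  # (rnaseq gene, truth gene)
    n_unmatched_expr: int
    n_unmatched_truth: int


def match_to_truth(
    expr_genes: list[str], truth: TruthTable, idmap: IdentifierMap | None = None
) -> MatchToTruth:
    """One-to-one match of (filtered) RNA-seq genes to truth-table genes.

    Without a map, identity matching on gene_id is used. Many-to-many map
    rows are dropped, as in cross-annotation matching.
    """
    truth_genes = set(truth.gene_ids)
    expr_set = set(expr_genes)
    if idmap is None:
        pairs = [(g, g) for g in expr_genes if g in truth_genes]
    else:
        present = [(x, y) for x, y in dict.fromkeys(idmap.pairs) if x in expr_set and y in truth_genes]
        deg_a: dict[str, int] = {}
        deg_b: dict[str, int] = {}
        for x, y in present:
            deg_a[x] = deg_a.get(x, 0) + 1
            deg_b[y] = deg_b.get(y, 0) + 1
        pairs = [(x, y) for x, y in present if deg_a[x] == 1 and deg_b[y] == 1]
    matched_expr = {x for x, _ in pairs}
    matched_truth = {y for _, y in pairs}
    return MatchToTruth(
        matched=sorted(pairs),
        n_unmatched_expr=len(expr_set - matched_expr),
        n_unmatched_truth=len(truth_genes - matched_truth),
    )


@dataclass
class CorrelationReport:
    """Pearson r per sample for one (platform, normalization, gene-set mode)."""

    platform: str
    normalization: str
    gene_set_mode: str  # 'per-annotation' or 'common'
    n_genes: int
    r_by_sample: dict[str, float] = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        return [
            {
                "platform": self.platform,
                "normalization": self.normalization,
                "gene_set_mode": self.gene_set_mode,
                "sample": sample,
                "pearson_r": r,
                "n_genes": self.n_genes,
            }
            for sample, r in self.r_by_sample.items()
        ]


def pearson_validation(
    expr: ExpressionMatrix,
    truth: TruthTable,
    matches: MatchToTruth,
    design: MixtureDesign,
    gene_set_mode: str = "per-annotation",
) -> CorrelationReport:
    """Per-sample Pearson correlation between RNA-seq and truth expression.

    RNA-seq replicates are averaged (log2 scale) per sample first; the
    correlation runs across matched genes. Requires >=3 matched genes; a
    zero-variance side yields NaN with a warning.
    """
    if len(matches.matched) < 3:
        raise ValueError(f"need >=3 matched genes, have {len(matches.matched)}")
    truth_tab = collapse_probes(truth)
    means = replicate_mean_expression(expr, design)
    expr_idx = [x for x, _ in matches.matched]
    truth_idx = [y for _, y in matches.matched]
    report = CorrelationReport(
        platform=truth.platform,
        normalization=expr.normalization,
        gene_set_mode=gene_set_mode,
        n_genes=len(matches.matched),
    )
    for sample in design.samples:
        if sample not in truth_tab.data.columns:
            continue
        a = means.loc[expr_idx, sample].to_numpy()
        b = truth_tab.data.loc[truth_idx, sample].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            logger.warning("zero variance in sample %s; correlation undefined", sample)
            report.r_by_sample[sample] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = _st.pearsonr(a, b).statistic
        report.r_by_sample[sample] = float(r)
    return report


def write_correlation_reports(reports: list[CorrelationReport], path) -> None:
    rows = [row for rep in reports for row in rep.as_rows()]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write(
                f"{row.platform}\t{row.normalization}\t{row.gene_set_mode}\t{row['sample']}\t"
                f"{row.pearson_r:.10g}\t{row.n_genes}\n"
            )
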