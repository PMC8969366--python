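"""Titration-monotonicity assessment for mixture designs.

Samples C and D are linear mixtures of reference samples A and B (default
3:1 and 1:3). Under that design, a gene whose A-vs-B log2 fold-change is x
has an expected C-vs-D log2 fold-change of

    E(x) = log2((p*2^x + (1-p)) / (q*2^x + (1-q)))

with mixing proportions p (A in C) and q (A in D); at the default
p=0.75, q=0.25 this is log2((3*2^x + 1)/(2^x + 3)), bounded by +-log2 3.
The assessment scores each gene's observed C-vs-D fold-change against E(x)
and summarizes with a mean squared error and the fraction of genes whose
means are ordered monotonically (A >= C >= D >= B or the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import ExpressionMatrix


@dataclass
class MixtureDesign:
    """Sample composition (fraction of A, fraction of B) and replicate map."""

    proportions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (1.0, 0.0),
            "B": (0.0, 1.0),
            "C": (0.75, 0.25),
            "D": (0.25, 0.75),
        }
    )
    replicate_map: dict[str, str] = field(default_factory=dict)  # library -> sample

    def __post_init__(self) -> None:
        for sample, (pa, pb) in self.proportions.items():
            if not (0 <= pa <= 1 and 0 <= pb <= 1) or abs(pa + pb - 1) > 1e-9:
                raise ValueError(f"sample {sample}: proportions must be in [0,1] and sum to 1")

    @classmethod
    def seqc_default(cls, replicates: int = 4) -> "MixtureDesign":
        design = cls()
        design.replicate_map = {
            f"{s}_{r + 1}": s for s in ("A", "B", "C", "D") for r in range(replicates)
        }
        return design

    @property
    def samples(self) -> list[str]:
        return list(self.proportions)

    def libraries_of(self, sample: str) -> list[str]:
        return [lib for lib, s in self.replicate_map.items() if s == sample]


def expected_log2fc(x, p: float = 0.75, q: float = 0.25):
    """Expected C-vs-D log2 fold-change given A-vs-B log2 fold-change x."""
    if not (0 < p < 1 and 0 < q < 1):
        raise ValueError("mixing proportions must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        two_x = np.exp2(x)
        out = np.log2((p * two_x + (1 - p)) / (q * two_x + (1 - q)))
    # analytic asymptotes where 2^x overflows
    out = np.where(np.isposinf(two_x), np.log2(p / q), out)
    out = np.where(np.isneginf(x), np.log2((1 - p) / (1 - q)), out)
    return out if out.ndim else float(out)


def replicate_mean_expression(expr: ExpressionMatrix, design: MixtureDesign) -> pd.DataFrame:
    """Per-gene arithmetic mean over each sample's replicate libraries.

    Averaging happens on the matrix's stated (log2) scale.
    """
    unmapped = [lib for lib in expr.library_ids if lib not in design.replicate_map]
    if unmapped:
        raise ValueError(f"libraries not mapped to a sample: {unmapped}")
    df = expr.to_dataframe()
    out = {}
    for sample in design.samples:
        libs = [lib for lib in expr.library_ids if design.replicate_map[lib] == sample]
        if not libs:
            raise ValueError(f"sample {sample} has no libraries")
        out[sample] = df[libs].mean(axis=1)
    return pd.DataFrame(out)


def observed_log2fc(means: pd.DataFrame, s1: str, s2: str) -> pd.Series:
    """Per-gene log2 fold-change between two samples of a log2-scale matrix."""
    for s in (s1, s2):
        if s not in means.columns:
            raise ValueError(f"unknown sample {s!r}")
    return means[s1] - means[s2]


def monotonicity_preserved(means: pd.DataFrame) -> pd.Series:
    """Per-gene flag: sample means ordered A >= C >= D >= B or A <= C <= D <= B.

    Inequalities are non-strict, so a flat gene (A=B=C=D) is monotone.
    """
    a, b, c, d = (means[s] for s in ("A", "B", "C", "D"))
    down = (a >= c) & (c >= d) & (d >= b)
    up = (a <= c) & (c <= d) & (d <= b)
    return down | up


def titration_mse(x: pd.Series, observed_cd: pd.Series, p: float = 0.75, q: float = 0.25) -> float:
    """Mean squared error between observed C-vs-D fold-changes and E(x).

    Computed over genes where both x and the observed value are finite.
    """
    finite = np.isfinite(x) & np.isfinite(observed_cd)
    if not finite.any():
        raise ValueError("no genes with finite fold changes")
    resid = observed_cd[finite] - expected_log2fc(x[finite].to_numpy(), p=p, q=q)
    return float(np.mean(np.square(resid)))


@dataclass
class TitrationAssessment:
    """Per-gene titration table plus MSE and monotone-fraction summary."""

    per_gene: pd.DataFrame  # columns: x, observed_cd, expected_cd, monotonic
    mse: float
    monotone_fraction: float
    n_genes: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tx\tobserved_cd\texpected_cd\tmonotonic\n")
            for gid, row in self.per_gene.iterrows():
                fh.write(
                    f"{gid}\t{row.x:.10g}\t{row.observed_cd:.10g}\t"
                    f"{row.expected_cd:.10g}\t{int(row.monotonic)}\n"
                )

    def summary(self) -> dict:
        return {"mse": self.mse, "monotone_fraction": self.monotone_fraction, "n_genes": self.n_genes}


def assess_titration(
    expr: ExpressionMatrix,
    design: MixtureDesign,
    gene_ids: list[str] | None = None,
    p: float = 0.75,
    q: float = 0.25,
) -> TitrationAssessment:
    """Run the full titration assessment on an expression matrix.

    ``gene_ids`` restricts the gene set (all genes / filtered genes / common
    genes); fold changes are differences of replicate-averaged log2 values.
    """
    if gene_ids is not None:
        expr = expr.select_genes(gene_ids)
    means = replicate_mean_expression(expr, design)
    x = observed_log2fc(means, "A", "B")
    observed_cd = observed_log2fc(means, "C", "D")
    expected_cd = pd.Series(expected_log2fc(x.to_numpy(), p=p, q=q), index=x.index)
    monotonic = monotonicity_preserved(means)
    finite = np.isfinite(x) & np.isfinite(observed_cd)
    per_gene = pd.DataFrame(
        {"x": x, "observed_cd": observed_cd, "expected_cd": expected_cd, "monotonic": monotonic}
    )
    mse = titration_mse(x, observed_cd, p=p, q=q)
    return TitrationAssessment(
        per_gene=per_gene,
        mse=mse,
        monotone_fraction=float(monotonic[finite].mean()),
        n_genes=int(finite.sum()),
    )
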