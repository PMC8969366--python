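"""Count-to-expression conversion and between-library normalization.

Counts become log2CPM with voom-style offsets (prior count 0.5 on counts,
+1 on the effective library size), optionally quantile-normalized on the
log scale or scaled by TMM factors; log2FPKM subtracts log2(effective
length / 1000). The expression filter keeps genes reaching a CPM threshold
(prior 0, raw library sizes) in a minimum number of libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .counting import CountMatrix


@dataclass
class NormalizationFactors:
    """Per-library positive scaling factors with geometric mean 1."""

    library_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1 (got {gm})")

    @classmethod
    def unit(cls, library_ids: list[str]) -> "NormalizationFactors":
        return cls(library_ids=list(library_ids), factors=np.ones(len(library_ids)))


@dataclass
class ExpressionMatrix:
    """Genes x libraries real expression values with scale/normalization tags."""

    gene_ids: list[str]
    library_ids: list[str]
    values: np.ndarray
    scale: str  # 'log2CPM' or 'log2FPKM'
    normalization: str  # 'library_size', 'quantile' or 'TMM'
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ValueError("expression matrix shape mismatch")
        if self.scale not in ("log2CPM", "log2FPKM"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.normalization not in ("library_size", "quantile", "TMM"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.library_ids)

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        idx = [self.gene_ids.index(g) for g in keep] if len(keep) < len(self.gene_ids) else None
        values = self.values if idx is None else self.values[idx]
        return ExpressionMatrix(
            gene_ids=keep,
            library_ids=list(self.library_ids),
            values=values,
            scale=self.scale,
            normalization=self.normalization,
            prior_count=self.prior_count,
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scale={self.scale}\tnormalization={self.normalization}\tprior={self.prior_count:g}\n")
            fh.write("gene_id\t" + "\t".join(self.library_ids) + "\n")
            for i, gid in enumerate(self.gene_ids):
                fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in self.values[i]) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
        return cls(
            gene_ids=list(df.index),
            library_ids=list(df.columns),
            values=df.to_numpy(),
            scale=meta["scale"],
            normalization=meta["normalization"],
            prior_count=float(meta["prior"]),
        )


# ---------------------------------------------------------------------------


def cpm(counts: CountMatrix, prior: float = 0.0) -> np.ndarray:
    """Counts per million assigned fragments: (count + prior)/libsize * 1e6."""
    libsize = counts.library_sizes.astype(float)
    zero = np.where(libsize == 0)[0]
    if zero.size:
        raise ValueError(f"zero library size for {[counts.library_ids[i] for i in zero]}")
    return (counts.counts + prior) / libsize * 1e6


def log2cpm(
    counts: CountMatrix,
    factors: NormalizationFactors | None = None,
    prior: float = 0.5,
    voom_offsets: bool = True,
) -> ExpressionMatrix:
    """voom-style log2CPM: log2((count + prior) / (libsize*factor + 1) * 1e6).

    With ``voom_offsets=False`` the +1 library-size offset is dropped.
    """
    libsize = counts.library_sizes.astype(float)
    if (libsize == 0).any():
        bad = [counts.library_ids[i] for i in np.where(libsize == 0)[0]]
        raise ValueError(f"zero library size for {bad}")
    f = np.ones(len(counts.library_ids)) if factors is None else factors.factors
    denom = libsize * f + (1.0 if voom_offsets else 0.0)
    values = np.log2((counts.counts + prior) / denom * 1e6)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        library_ids=list(counts.library_ids),
        values=values,
        scale="log2CPM",
        normalization="library_size" if factors is None else "TMM",
        prior_count=prior,
    )


def log2fpkm(expr: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Convert log2CPM to log2FPKM: subtract log2(effective length / 1000)."""
    if expr.scale != "log2CPM":
        raise ValueError("log2fpkm expects a log2CPM matrix")
    missing = [g for g in expr.gene_ids if g not in lengths]
    if missing:
        raise ValueError(f"missing effective length for genes: {missing[:5]}...")
    offset = np.array([math.log2(lengths[g] / 1000.0) for g in expr.gene_ids])
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        library_ids=list(expr.library_ids),
        values=expr.values - offset[:, None],
        scale="log2FPKM",
        normalization=expr.normalization,
        prior_count=expr.prior_count,
    )


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    Reference library: the one whose upper-quartile CPM is closest to the
    mean upper-quartile. Per library, M (log2 ratio vs reference) and A
    (average log2 abundance) are computed over genes positive in both
    libraries; the stated fractions of extreme M and A ranks are trimmed;
    the factor is 2 to the variance-weighted mean of the surviving M values
    (weights = inverse asymptotic binomial variance). Factors are rescaled
    to geometric mean 1.
    """
    x = counts.counts.astype(float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("TMM undefined with an all-zero library")
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])]) * 1e6
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    raw = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        raw[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], logratio_trim, abs_trim,
                           library_label=counts.library_ids[j])
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(library_ids=list(counts.library_ids), factors=factors)


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abs_trim, library_label="") -> float:
    import logging

    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        logging.getLogger(__name__).warning(
            "library %s shares no positive genes with the TMM reference; factor set to 1",
            library_label,
        )
        return 1.0
    obs = obs[keep]
    ref = ref[keep]
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = _st.rankdata(m)
    rank_a = _st.rankdata(a)
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.nansum(m[keep2] / v[keep2]) / np.nansum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns: sorted values become the rank means.

    Ties within a column receive the mean of the rank means they span.
    Idempotent; equivariant under row permutation.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize: missing values not supported")
    n, k = values.shape
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        # average target over tie groups
        sorted_col = col[order]
        result_sorted = target.copy()
        start = 0
        for i in range(1, n + 1):
            if i == n or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    result_sorted[start:i] = target[start:i].mean()
                start = i
        out[:, j] = result_sorted[ranks]
    return out


def quantile_normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a log-scale expression matrix (columns)."""
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        library_ids=list(expr.library_ids),
        values=quantile_normalize(expr.values),
        scale=expr.scale,
        normalization="quantile",
        prior_count=expr.prior_count,
    )


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 0.5, min_libraries: int = 4
) -> list[str]:
    """Gene ids retained by the expression filter.

    A gene is kept iff its CPM (prior 0, raw library sizes) is >= ``min_cpm``
    in at least ``min_libraries`` libraries; both bounds inclusive.
    """
    c = cpm(counts, prior=0.0)
    n_ok = (c >= min_cpm).sum(axis=1)
    return [g for g, n in zip(counts.gene_ids, n_ok) if n >= min_libraries]


def intensity_range_summary(expr: ExpressionMatrix) -> pd.DataFrame:
    """Boxplot statistics per library: median, quartiles, IQR, whiskers.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    values within 1.5 IQR of the quartiles (Tukey convention).
    """
    rows = []
    for j, lib in enumerate(expr.library_ids):
        col = expr.values[:, j]
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        iqr = q3 - q1
        lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = col[(col >= lo_bound) & (col <= hi_bound)]
        rows.append((lib, med, q1, q3, iqr, inside.min(), inside.max()))
    return pd.DataFrame(
        rows,
        columns=["library_id", "median", "q1", "q3", "iqr", "whisker_low", "whisker_high"],
    ).set_index("library_id")
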