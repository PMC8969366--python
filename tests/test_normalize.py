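"""Normalization: CPM/FPKM transforms, TMM factors, quantile, filtering."""

import math

import numpy as np
import pytest

from annoquant.counting import CountMatrix
from annoquant.normalize import (
    ExpressionMatrix,
    cpm,
    filter_low_expression,
    intensity_range_summary,
    log2cpm,
    log2fpkm,
    quantile_normalize,
    tmm_factors,
)


def make_counts(matrix, lengths=None):
    matrix = np.asarray(matrix)
    gene_ids = [f"g{i}" for i in range(matrix.shape[0])]
    return CountMatrix(
        gene_ids=gene_ids,
        library_ids=[f"l{j}" for j in range(matrix.shape[1])],
        counts=matrix,
        lengths=lengths or {g: 1000 for g in gene_ids},
    )


def random_nb_counts(rng, n_genes=300, n_libs=5):
    mu = rng.lognormal(4, 1.5, size=n_genes)
    scale = rng.uniform(0.5, 2.0, size=n_libs)
    return rng.negative_binomial(5, 5 / (5 + mu[:, None] * scale), size=(n_genes, n_libs))


# ---------------------------------------------------------------------------
# Independent step-by-step TMM oracle (plain Python, no shared helpers)


def tmm_oracle(counts):
    counts = np.asarray(counts, dtype=float)
    n_genes, n_libs = counts.shape
    lib = counts.sum(axis=0)
    # reference: upper-quartile CPM closest to the mean upper-quartile
    uqs = []
    for j in range(n_libs):
        col = sorted(counts[:, j] / lib[j] * 1e6)
        # linear-interpolation quantile, as numpy default
        pos = 0.75 * (n_genes - 1)
        lo, hi = int(math.floor(pos)), int(math.ceil(pos))
        uqs.append(col[lo] + (pos - lo) * (col[hi] - col[lo]))
    mean_uq = sum(uqs) / n_libs
    ref = min(range(n_libs), key=lambda j: abs(uqs[j] - mean_uq))

    factors = []
    for j in range(n_libs):
        if j == ref:
            factors.append(1.0)
            continue
        ms, aas, ws = [], [], []
        for g in range(n_genes):
            o, r = counts[g, j], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            ms.append(math.log2(po / pr))
            aas.append(0.5 * math.log2(po * pr))
            ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(ms)
        if n == 0 or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue

        def ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            rk = [0.0] * n
            i = 0
            while i < n:
                jj = i
                while jj + 1 < n and vals[order[jj + 1]] == vals[order[i]]:
                    jj += 1
                avg = (i + jj) / 2 + 1
                for k in range(i, jj + 1):
                    rk[order[k]] = avg
                i = jj + 1
            return rk

        rm, ra = ranks(ms), ranks(aas)
        lo_l, hi_l = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_s, hi_s = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        num = den = 0.0
        for i in range(n):
            if lo_l <= rm[i] <= hi_l and lo_s <= ra[i] <= hi_s:
                num += ms[i] / ws[i]
                den += 1 / ws[i]
        factors.append(2 ** (num / den) if den else 1.0)
    log_gm = sum(math.log(f) for f in factors) / n_libs
    return [f / math.exp(log_gm) for f in factors]


# ---------------------------------------------------------------------------


class TestCpm:
    def test_unit_example(self):
        cm = make_counts([[1], [10 ** 6 - 1]])
        assert cpm(cm)[0, 0] == pytest.approx(1.0)

    def test_all_zero_gene(self):
        cm = make_counts([[0, 0], [10, 20]])
        assert (cpm(cm)[0] == 0).all()

    def test_columns_sum_to_million(self, rng):
        cm = make_counts(rng.integers(0, 500, size=(50, 4)) + 1)
        np.testing.assert_allclose(cpm(cm).sum(axis=0), 1e6)

    def test_zero_library_size_errors(self):
        cm = make_counts([[0, 5]])
        with pytest.raises(ValueError, match="l0"):
            cpm(cm)


class TestLog2Cpm:
    def test_voom_formula_at_zero_count(self):
        # count 0, prior 0.5, libsize 1e6 - 1, factor 1 -> log2(0.5) = -1
        cm = make_counts([[0], [10 ** 6 - 1]])
        expr = log2cpm(cm)
        assert expr.values[0, 0] == pytest.approx(-1.0)

    def test_scaling_invariance_up_to_offset(self, rng):
        base = rng.integers(1, 1000, size=(100, 3)) + 1000
        cm1 = make_counts(base)
        cm2 = make_counts(base * 2)
        # make library sizes >= 1e6 so the +1 offset is negligible
        pad = np.full((1, 3), 2_000_000)
        cm1 = make_counts(np.vstack([base, pad]))
        cm2 = make_counts(np.vstack([base * 2, pad * 2]))
        e1 = log2cpm(cm1).values[:-1]
        e2 = log2cpm(cm2).values[:-1]
        # doubling counts doubles the numerator and the library size;
        # only the prior and +1 offsets break exact equality
        assert np.abs(e1 - e2).max() < 1e-3

    def test_unit_factors_match_library_size(self, rng):
        from annoquant.normalize import NormalizationFactors

        cm = make_counts(rng.integers(0, 100, size=(30, 4)) + 1)
        f = NormalizationFactors.unit(cm.library_ids)
        np.testing.assert_allclose(log2cpm(cm, factors=f).values, log2cpm(cm).values)


class TestLog2Fpkm:
    def test_length_1000_identity(self):
        cm = make_counts([[100], [900]])
        expr = log2cpm(cm)
        fpkm = log2fpkm(expr, {"g0": 1000, "g1": 1000})
        np.testing.assert_allclose(fpkm.values, expr.values)

    def test_length_2000_subtracts_one(self):
        cm = make_counts([[100], [900]])
        expr = log2cpm(cm)
        fpkm = log2fpkm(expr, {"g0": 2000, "g1": 1000})
        assert fpkm.values[0, 0] == pytest.approx(expr.values[0, 0] - 1)

    def test_round_trip_exact(self, rng):
        cm = make_counts(rng.integers(0, 1000, size=(40, 3)) + 1)
        lengths = {g: int(L) for g, L in zip(cm.gene_ids, rng.integers(200, 9000, size=40))}
        expr = log2cpm(cm)
        fpkm = log2fpkm(expr, lengths)
        offset = np.array([np.log2(lengths[g] / 1000) for g in cm.gene_ids])
        np.testing.assert_allclose(fpkm.values + offset[:, None], expr.values, atol=1e-12)

    def test_missing_length_errors(self):
        cm = make_counts([[100], [900]])
        with pytest.raises(ValueError, match="g1"):
            log2fpkm(log2cpm(cm), {"g0": 1000})


class TestTmm:
    def test_identical_libraries(self):
        col = np.arange(1, 51)
        cm = make_counts(np.column_stack([col, col, col]))
        np.testing.assert_allclose(tmm_factors(cm).factors, 1.0)

    def test_doubled_library(self):
        col = np.arange(1, 51)
        cm = make_counts(np.column_stack([col, col * 2]))
        np.testing.assert_allclose(tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(5):
            counts = random_nb_counts(rng)
            cm = make_counts(counts)
            mine = tmm_factors(cm).factors
            oracle = tmm_oracle(counts)
            np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_near_invariant_to_single_library_scaling(self, rng):
        # M and A values are scale-free; only the inverse-binomial weights
        # shift slightly when one library is rescaled with its size
        counts = random_nb_counts(rng, n_genes=200, n_libs=4)
        cm1 = make_counts(counts)
        scaled = counts.copy()
        scaled[:, 2] *= 3
        cm2 = make_counts(scaled)
        np.testing.assert_allclose(tmm_factors(cm1).factors, tmm_factors(cm2).factors, atol=0.01)

    def test_geometric_mean_one(self, rng):
        f = tmm_factors(make_counts(random_nb_counts(rng))).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(size=30)
        values = np.column_stack([col, col])
        np.testing.assert_allclose(quantile_normalize(values), values)

    def test_worked_2x2_example(self):
        values = np.array([[1.0, 3.0], [2.0, 4.0]])
        out = quantile_normalize(values)
        np.testing.assert_allclose(out, [[2.0, 2.0], [3.0, 3.0]])

    def test_columns_share_sorted_values(self, rng):
        values = rng.normal(size=(50, 4))
        out = quantile_normalize(values)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self, rng):
        values = rng.normal(size=(40, 3))
        once = quantile_normalize(values)
        np.testing.assert_allclose(quantile_normalize(once), once)

    def test_row_permutation_equivariant(self, rng):
        values = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            quantile_normalize(values[perm]), quantile_normalize(values)[perm]
        )

    def test_ties_get_mean_of_spanned_rank_means(self):
        values = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(values)
        # rank means: (5.5, 10.5, 17.5); tied pair spans ranks 1-2
        np.testing.assert_allclose(out[:, 0], [8.0, 8.0, 17.5])
        np.testing.assert_allclose(out[:, 1], [5.5, 10.5, 17.5])


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = np.vstack([[0] * 6, np.full((5, 6), 1000)])
        assert "g0" not in filter_low_expression(make_counts(counts))

    def test_boundary_three_libraries_removed(self):
        # CPM exactly 1.0 in 3 libraries, 0 elsewhere -> removed at default 4
        base = np.full((2, 6), 500_000)
        gene = np.array([[1, 1, 1, 0, 0, 0]])  # libsize ~1e6 -> CPM ~1
        counts = np.vstack([gene, base])
        kept = filter_low_expression(make_counts(counts))
        assert "g0" not in kept

    def test_boundary_exact_half_cpm_in_four_retained(self):
        # library sizes exactly 2e6, so CPM is exactly 0.5 in four libraries
        base = np.array([[2_000_000 - 1] * 4 + [2_000_000] * 2])
        gene = np.array([[1, 1, 1, 1, 0, 0]])
        counts = np.vstack([gene, base])
        cm = make_counts(counts)
        np.testing.assert_allclose(cpm(cm)[0, :4], 0.5)
        assert "g0" in filter_low_expression(cm)

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 8, size=(100, 6))
        counts[0] = 1000  # keep library sizes positive
        cm = make_counts(counts)
        kept = set(filter_low_expression(cm, min_cpm=0.5, min_libraries=4))
        lib = counts.sum(axis=0)
        for i, g in enumerate(cm.gene_ids):
            n_ok = sum(counts[i, j] / lib[j] * 1e6 >= 0.5 for j in range(6))
            assert (g in kept) == (n_ok >= 4)


class TestIntensitySummary:
    def make_expr(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(values.shape[0])],
            library_ids=[f"l{j}" for j in range(values.shape[1])],
            values=values,
            scale="log2FPKM",
            normalization="library_size",
        )

    def test_constant_column(self):
        summary = intensity_range_summary(self.make_expr(np.ones((10, 1))))
        assert summary.loc["l0", "iqr"] == 0

    def test_one_to_five(self):
        summary = intensity_range_summary(self.make_expr(np.arange(1, 6)[:, None]))
        assert summary.loc["l0", "median"] == 3
        assert summary.loc["l0", "iqr"] == 2

    def test_doubled_spread(self, rng):
        col = rng.normal(size=200)
        summary = intensity_range_summary(self.make_expr(np.column_stack([col, col * 2])))
        assert summary.loc["l1", "iqr"] > summary.loc["l0", "iqr"]


def test_expression_tsv_round_trip(tmp_path, rng):
    cm = make_counts(rng.integers(1, 100, size=(10, 3)))
    expr = log2cpm(cm)
    path = tmp_path / "expr.tsv"
    expr.write_tsv(path)
    back = ExpressionMatrix.read_tsv(path)
    assert back.scale == expr.scale and back.normalization == expr.normalization
    np.testing.assert_allclose(back.values, expr.values, rtol=1e-9)
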