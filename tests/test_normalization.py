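"""TMM factors, CPM scaling, abundance filtering, fold-change tensor."""

from __future__ import annotations

import subprocess

import numpy as np
import pandas as pd
import pytest

from transgressnet import (
    CountMatrix,
    DegenerateInputError,
    UsageError,
    fold_change_tensor,
    low_abundance_mask,
    normalize,
    tmm_factors,
)

from conftest import make_samples, random_count_matrix


def _matrix(columns: dict[str, list[int]], times=None) -> CountMatrix:
    names = list(columns)
    times = times or [0] * len(names)
    samples = make_samples(("A",), (0,), replicates=1)[:0]
    from transgressnet import SampleAnnotation

    samples = [
        SampleAnnotation(n, "A", times[i], i + 1) for i, n in enumerate(names)
    ]
    table = pd.DataFrame(
        columns, index=pd.Index([f"g{i}" for i in range(len(next(iter(columns.values()))))])
    )
    return CountMatrix(table, samples)


def reference_tmm(counts: np.ndarray, ref: int, sample: int,
                  trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Independent oracle: direct evaluation of the doubly-trimmed,
    precision-weighted mean of M values, written from the definition."""
    lib = counts.sum(axis=0)
    y, r = counts[:, sample].astype(float), counts[:, ref].astype(float)
    keep = (y > 0) & (r > 0)
    y, r = y[keep], r[keep]
    m = np.log2((y / lib[sample]) / (r / lib[ref]))
    a = 0.5 * np.log2((y / lib[sample]) * (r / lib[ref]))
    w = (lib[sample] - y) / (lib[sample] * y) + (lib[ref] - r) / (lib[ref] * r)
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = np.argsort(np.argsort(m)) + 1
    rank_a = np.argsort(np.argsort(a)) + 1
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    return float(2 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])))


class TestTmmFactors:
    def test_identical_columns_all_one(self):
        mat = _matrix({"s1": [10, 20, 30], "s2": [10, 20, 30], "s3": [10, 20, 30]})
        factors = tmm_factors(mat)
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-9)

    def test_pure_depth_scaling_absorbed(self):
        mat = _matrix({"s1": [10, 20, 30, 5], "s2": [100, 200, 300, 50]})
        factors = tmm_factors(mat)
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mat = random_count_matrix(rng, n_genes=50)
            f = tmm_factors(mat).to_numpy()
            assert np.mean(np.log(f)) == pytest.approx(0.0, abs=1e-12)

    def test_composition_shift_toy_matches_oracle(self):
        # sample B repeats A's profile but adds one dominant gene
        cols = {
            "A": [100, 200, 300, 400, 500, 100],
            "B": [110, 190, 310, 390, 520, 10000],
        }
        mat = _matrix(cols)
        counts = mat.counts.to_numpy(dtype=float)
        lib = counts.sum(axis=0)
        f75 = np.array([np.quantile(counts[:, s], 0.75) / lib[s] for s in range(2)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        other = 1 - ref
        expected = reference_tmm(counts, ref, other)
        raw = np.ones(2)
        raw[other] = expected
        expected_factors = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(
            tmm_factors(mat).to_numpy(), expected_factors, rtol=1e-12
        )

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        mat = random_count_matrix(rng, n_genes=60)
        scaled = CountMatrix(mat.counts * 7, mat.samples)
        np.testing.assert_allclose(
            tmm_factors(mat).to_numpy(), tmm_factors(scaled).to_numpy(), atol=1e-9
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        mat = random_count_matrix(rng, n_genes=60, genotypes=("A", "B"), replicates=2)
        order = rng.permutation(len(mat.samples))
        permuted = CountMatrix(
            mat.counts.iloc[:, order], [mat.samples[i] for i in order]
        )
        f = tmm_factors(mat)
        fp = tmm_factors(permuted)
        np.testing.assert_allclose(
            f.reindex(fp.index).to_numpy(), fp.to_numpy(), atol=1e-12
        )

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against Bioconductor edgeR's calcNormFactors."""
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(5, 0.02, size=(200, 6))
        counts[:10, 3] *= 50
        mat = _matrix({f"s{i}": counts[:, i].tolist() for i in range(6)})
        path = tmp_path / "counts.tsv"
        mat.counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR)); '
            f'x <- as.matrix(read.delim("{path}", row.names=1)); '
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in proc.stdout.split()])
        np.testing.assert_allclose(tmm_factors(mat).to_numpy(), reference, atol=1e-9)

    def test_fewer_than_two_samples_rejected(self):
        mat = _matrix({"s1": [1, 2, 3]})
        with pytest.raises(UsageError):
            tmm_factors(mat)

    def test_disjoint_support_names_pair(self):
        mat = _matrix({"s1": [10, 0, 5], "s2": [0, 10, 0]})
        with pytest.raises(DegenerateInputError, match="s"):
            tmm_factors(mat)


class TestNormalize:
    def test_cpm_identity(self):
        counts = {"s1": [100] + [0] * 9, "s2": [100] + [0] * 9}
        counts["s1"][1] = 10**6 - 100
        counts["s2"][1] = 10**6 - 100
        mat = _matrix(counts)
        factors = pd.Series([1.0, 1.0], index=["s1", "s2"])
        norm = normalize(mat, factors)
        assert norm.values.iloc[0, 0] == pytest.approx(100.0)

    def test_factor_two_halves_values(self):
        mat = _matrix({"s1": [10, 20], "s2": [10, 20]})
        one = normalize(mat, pd.Series([1.0, 1.0], index=["s1", "s2"]))
        # geometric-mean-1 pair (2, 1/2): factor 2 halves sample 1 relative
        # to factor 1, modulo the shared rescaling
        two = normalize(mat, pd.Series([2.0, 0.5], index=["s1", "s2"]))
        np.testing.assert_allclose(
            two.values["s1"].to_numpy(), one.values["s1"].to_numpy() / 2
        )

    def test_matches_cell_oracle(self):
        rng = np.random.default_rng(7)
        mat = random_count_matrix(rng, n_genes=20, genotypes=("A", "B", "C"))
        factors = tmm_factors(mat)
        norm = normalize(mat, factors)
        counts = mat.counts.to_numpy(dtype=float)
        lib = counts.sum(axis=0)
        for i in range(counts.shape[0]):
            for j in range(counts.shape[1]):
                expected = counts[i, j] / (lib[j] * factors.iloc[j]) * 1e6
                assert norm.values.iloc[i, j] == pytest.approx(expected, rel=1e-12)


class TestLowAbundanceMask:
    def test_all_zero_gene_excluded(self):
        mat = _matrix({"s1": [0, 10], "s2": [0, 10]})
        norm = normalize(mat, pd.Series([1.0, 1.0], index=["s1", "s2"]))
        mask = low_abundance_mask(norm, cutoff=1.0, min_samples=2)
        assert not mask.iloc[0] and mask.iloc[1]

    def test_boundary_is_inclusive(self):
        values = pd.DataFrame(
            {"s1": [1.0, 0.999], "s2": [1.0, 0.999]}, index=["g0", "g1"]
        )
        from transgressnet import NormalizedMatrix, SampleAnnotation

        norm = NormalizedMatrix(
            values=values,
            samples=[
                SampleAnnotation("s1", "A", 0, 1),
                SampleAnnotation("s2", "A", 0, 2),
            ],
            factors=pd.Series([1.0, 1.0], index=["s1", "s2"]),
            library_sizes=pd.Series([100, 100], index=["s1", "s2"]),
        )
        mask = low_abundance_mask(norm, cutoff=1.0, min_samples=2)
        assert mask.iloc[0] and not mask.iloc[1]

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(8)
        mat = random_count_matrix(rng, n_genes=40, genotypes=("A", "B"), replicates=2)
        norm = normalize(mat, tmm_factors(mat))
        mask = low_abundance_mask(norm, cutoff=5.0, min_samples=3)
        v = norm.values.to_numpy()
        expected = (v >= 5.0).sum(axis=1) >= 3
        np.testing.assert_array_equal(mask.to_numpy(), expected)


class TestFoldChangeTensor:
    def test_equal_means_give_zero(self):
        mat = _matrix({"s1": [50, 10], "s2": [50, 10]}, times=[0, 24])
        norm = normalize(mat, pd.Series([1.0, 1.0], index=["s1", "s2"]))
        tensor = fold_change_tensor(norm)
        np.testing.assert_allclose(tensor.fc.to_numpy(), 0.0, atol=1e-12)

    def test_pseudocount_arithmetic(self):
        # control mean 3, stress mean 15, pseudocount 1 -> log2(16/4) = 2
        from transgressnet import NormalizedMatrix, SampleAnnotation

        values = pd.DataFrame({"c": [3.0], "t": [15.0]}, index=["g0"])
        norm = NormalizedMatrix(
            values=values,
            samples=[
                SampleAnnotation("c", "A", 0, 1),
                SampleAnnotation("t", "A", 24, 1),
            ],
            factors=pd.Series([1.0, 1.0], index=["c", "t"]),
            library_sizes=pd.Series([100, 100], index=["c", "t"]),
        )
        tensor = fold_change_tensor(norm, pseudocount=1.0)
        assert tensor.fc.loc["g0", ("A", 24)] == pytest.approx(2.0)
        assert tensor.baseline.loc["g0", "A"] == pytest.approx(3.0)

    def test_matches_cell_oracle(self):
        rng = np.random.default_rng(9)
        mat = random_count_matrix(
            rng, n_genes=15, genotypes=("A", "B"), times=(0, 24, 48), replicates=2
        )
        norm = normalize(mat, tmm_factors(mat))
        tensor = fold_change_tensor(norm, pseudocount=1.0)
        for gene in tensor.gene_ids:
            for g in ("A", "B"):
                ctrl = [s.sample_id for s in norm.samples_for(g, 0)]
                ctrl_mean = norm.values.loc[gene, ctrl].mean()
                for t in (24, 48):
                    reps = [s.sample_id for s in norm.samples_for(g, t)]
                    expected = np.log2(norm.values.loc[gene, reps].mean() + 1) - np.log2(
                        ctrl_mean + 1
                    )
                    assert tensor.fc.loc[gene, (g, t)] == pytest.approx(expected, abs=1e-12)

    def test_missing_control_rejected(self):
        mat = _matrix({"s1": [1], "s2": [2]}, times=[24, 48])
        norm = normalize(mat, pd.Series([1.0, 1.0], index=["s1", "s2"]))
        with pytest.raises(UsageError, match="control"):
            fold_change_tensor(norm)

    def test_commutes_with_gene_subsetting(self):
        rng = np.random.default_rng(10)
        mat = random_count_matrix(rng, n_genes=30, genotypes=("A", "B"), replicates=2)
        norm = normalize(mat, tmm_factors(mat))
        from transgressnet import NormalizedMatrix

        full = fold_change_tensor(norm).subset_genes(["g0005", "g0001"])
        sub_norm = NormalizedMatrix(
            values=norm.values.loc[["g0005", "g0001"]],
            samples=norm.samples,
            factors=norm.factors,
            library_sizes=norm.library_sizes,
        )
        sub = fold_change_tensor(sub_norm)
        np.testing.assert_allclose(full.fc.to_numpy(), sub.fc.to_numpy(), atol=1e-12)
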