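"""Differential-expression statistics against formula and library oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fflhub import diffexpr as de
from fflhub.errors import (
    DegenerateVarianceError,
    InputMismatchError,
    InvalidConfigError,
    ValidationError,
)

import oracles


class TestWelch:
    def test_matches_direct_formula(self):
        t, df, p = de.welch_t([10, 11, 12, 13], [14, 15, 16, 17])
        t0, df0, p0 = oracles.welch_formula([10, 11, 12, 13], [14, 15, 16, 17])
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_identity_case(self):
        t, _, p = de.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_symmetric_equal_means(self):
        t, _, p = de.welch_t([4, 6], [3, 5, 7])
        assert t == 0.0
        assert p == 1.0

    def test_degenerate_groups(self):
        assert de.welch_t([5, 5, 5], [5, 5]) == (0.0, 3.0, 1.0)
        with pytest.raises(DegenerateVarianceError):
            de.welch_t([5, 5, 5], [6, 6])
        with pytest.raises(InvalidConfigError):
            de.welch_t([1], [2, 3])


class TestModeratedT:
    def test_zero_prior_recovers_pooled_t(self, small_matrix):
        matrix, phenotype = small_matrix
        table = de.moderated_t(matrix, phenotype, prior_df=0)
        a = matrix.iloc[:, :3].to_numpy()
        b = matrix.iloc[:, 3:].to_numpy()
        for i in range(len(matrix)):
            t0, p0 = stats.ttest_ind(a[i], b[i], equal_var=True)[:2]
            assert table["statistic"].iloc[i] == pytest.approx(t0, rel=1e-9)
            assert table["p_value"].iloc[i] == pytest.approx(p0, rel=1e-9)

    def test_identical_variances_shrink_to_themselves(self, rng):
        # all genes share one variance: the posterior variance estimate
        # should concentrate near that variance
        n_genes = 400
        values = rng.normal(0.0, 1.0, size=(n_genes, 10))
        matrix = pd.DataFrame(values, columns=[f"s{i}" for i in range(10)])
        phenotype = pd.Series(["case"] * 5 + ["control"] * 5, index=matrix.columns)
        table = de.moderated_t(matrix, phenotype)
        # moderated statistics should be close to per-gene pooled t but
        # with stabilised denominators: sd of statistics near 1 under null
        assert np.std(table["statistic"]) == pytest.approx(1.0, abs=0.15)

    def test_null_type_one_error_calibrated(self, rng):
        n_genes = 500
        values = rng.normal(5.0, rng.uniform(0.5, 1.5, size=(n_genes, 1)), size=(n_genes, 12))
        matrix = pd.DataFrame(values, columns=[f"s{i}" for i in range(12)])
        phenotype = pd.Series(["case"] * 6 + ["control"] * 6, index=matrix.columns)
        table = de.moderated_t(matrix, phenotype)
        frac = float((table["p_value"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) <= 3 * se

    def test_all_constant_rows_degenerate(self):
        matrix = pd.DataFrame(np.ones((12, 6)), columns=[f"s{i}" for i in range(6)])
        phenotype = pd.Series(["case"] * 3 + ["control"] * 3, index=matrix.columns)
        with pytest.raises(DegenerateVarianceError):
            de.moderated_t(matrix, phenotype)

    def test_agrees_with_limma_ebayes(self, rng, tmp_path):
        """Independent cross-check of the empirical-Bayes machinery."""
        n_genes, n1, n2 = 150, 6, 8
        sds = rng.uniform(0.4, 1.6, size=(n_genes, 1))
        values = rng.normal(7.0, 1.0, size=(n_genes, 1)) + rng.normal(
            0.0, sds, size=(n_genes, n1 + n2)
        )
        matrix = pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n1 + n2)],
        )
        phenotype = pd.Series(["case"] * n1 + ["control"] * n2, index=matrix.columns)
        mine = de.moderated_t(matrix, phenotype)

        data = tmp_path / "expr.tsv"
        out = tmp_path / "limma.tsv"
        matrix.to_csv(data, sep="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{data}", row.names=1))
        design <- cbind(Intercept=1, case=c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(x, design))
        write.table(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"]),
                    "{out}", sep="\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        assert np.corrcoef(mine["statistic"], ref["t"])[0, 1] > 0.9999
        assert np.max(np.abs(mine["statistic"] - ref["t"])) < 0.05


class TestRunDeg:
    def test_alpha_zero_yields_no_degs(self, small_matrix):
        matrix, phenotype = small_matrix
        table = de.run_deg(matrix, phenotype, alpha=0.0)
        assert de.deg_summary(table, alpha=0.0)["n_deg"] == 0
        assert set(table["direction"]) == {"none"}

    def test_unknown_sample_rejected(self, small_matrix):
        matrix, phenotype = small_matrix
        bad = pd.concat([phenotype, pd.Series({"ghost": "case"})])
        with pytest.raises(InputMismatchError):
            de.run_deg(matrix, bad)

    def test_up_down_partition_degs(self, rng):
        values = rng.normal(6.0, 0.4, size=(60, 10))
        values[:20, :5] += 2.0
        values[20:40, :5] -= 2.0
        matrix = pd.DataFrame(values, columns=[f"s{i}" for i in range(10)])
        phenotype = pd.Series(["case"] * 5 + ["control"] * 5, index=matrix.columns)
        table = de.run_deg(matrix, phenotype)
        counts = de.deg_summary(table)
        assert counts["n_up"] + counts["n_down"] == counts["n_deg"]
        assert (table["direction"].iloc[:20] == "up").all()
        assert (table["direction"].iloc[20:40] == "down").all()

    def test_permutation_equivariant(self, small_matrix, rng):
        matrix, phenotype = small_matrix
        perm = rng.permutation(matrix.columns)
        shuffled = de.run_deg(matrix[perm], phenotype[perm])
        reference = de.run_deg(matrix, phenotype)
        pd.testing.assert_frame_equal(shuffled, reference)

    def test_null_pvalues_uniform_ks(self):
        from fflhub.simulate import SimConfig, gen_expression

        cfg = SimConfig(n_genes=2000, de_fraction=0.0, seed=11)
        matrix, phenotype, _ = gen_expression(cfg)
        table = de.run_deg(matrix, phenotype)
        d = stats.kstest(table["p_value"], "uniform").statistic
        assert d < 1.63 / np.sqrt(2000)  # 1% critical value


class TestRowZscore:
    def test_simple_row(self):
        out = de.row_zscore(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.to_numpy()[0], [-1, 0, 1])

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning):
            out = de.row_zscore(pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert (out.iloc[0] == 0).all()

    def test_random_matrix_standardised(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(5, 6)))
        out = de.row_zscore(matrix).to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)


class TestHclust:
    def test_identical_rows_merge_at_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        dend = de.hclust_pearson_complete(matrix)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(dend.linkage[0, :2]) == {0, 1}

    def test_anticorrelated_blocks(self):
        a = [1.0, 2.0, 4.0]
        neg = [-1.0, -2.0, -4.0]
        matrix = pd.DataFrame([a, a, neg, neg])
        dend = de.hclust_pearson_complete(matrix)
        heights = dend.linkage[:, 2]
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert heights[1] == pytest.approx(0.0, abs=1e-12)
        assert heights[2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_scipy_oracle_on_random_rows(self, rng):
        values = rng.normal(size=(6, 7))
        dend = de.hclust_pearson_complete(pd.DataFrame(values))
        ref = oracles.hclust_scipy_oracle(values)
        np.testing.assert_allclose(
            np.sort(dend.linkage[:, 2]), np.sort(ref[:, 2]), atol=1e-10
        )

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            de.hclust_pearson_complete(pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


class TestWilcoxon:
    def test_exact_small_case(self):
        assert de.wilcoxon_ranksum([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_same_multiset_p_one(self):
        assert de.wilcoxon_ranksum([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            de.wilcoxon_ranksum([], [1.0])

    def test_exact_matches_independent_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            assert de.wilcoxon_ranksum(x, y) == pytest.approx(
                oracles.wilcoxon_exact_oracle(x, y)
            )

    def test_normal_approx_close_to_exact(self, rng):
        # 8 vs 8 exceeds the exact-enumeration cutoff: approximation path
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8) + 0.5
            approx = de.wilcoxon_ranksum(x, y)
            exact = oracles.wilcoxon_exact_oracle(x, y)
            assert abs(approx - exact) <= 0.02
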