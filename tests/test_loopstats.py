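import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopscape.io import SampleSheet
from loopscape import loopstats as ls


def sheet_for(cell_types, n_reps=2, groups=None):
    rows = []
    for i, ct in enumerate(cell_types):
        g = groups[i] if groups else ("blood" if i < 2 else "solid")
        for r in range(1, n_reps + 1):
            rows.append({"sample_id": f"{ct}_r{r}", "cell_type": ct, "replicate": r,
                         "group": g, "batch": "b1", "depth": 1000})
    return SampleSheet(pd.DataFrame(rows))


class TestFilterTestable:
    def test_threshold_boundaries(self):
        M = pd.DataFrame({"s1": [4, 3, 0], "s2": [0, 1, 0]}, index=["a", "b", "c"])
        kept = ls.filter_testable(M, min_pets=4)
        assert list(kept.index) == ["a"]
        assert ls.filter_testable(M, min_pets=0).equals(M)


class TestNormalize:
    def reference_pipeline(self, X):
        """Independent spreadsheet-style reimplementation (no ties assumed)."""
        X = np.asarray(X, dtype=float)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        ref = np.sort(Z, axis=0).mean(axis=1)
        Q = np.empty_like(Z)
        for j in range(Z.shape[1]):
            order = np.argsort(Z[:, j])
            Q[order, j] = ref
        R = (Q - Q.min(axis=0)) / (Q.max(axis=0) - Q.min(axis=0)) * 1000
        return R

    def test_matches_hand_computed_reference_on_3x3(self):
        M = pd.DataFrame([[1.0, 5.0, 3.5], [10.0, 2.0, 6.0], [4.0, 9.0, 2.0]],
                         columns=list("abc"))
        out = ls.normalize_matrix(M)
        assert np.allclose(out.to_numpy(), self.reference_pipeline(M.to_numpy()))

    def test_matches_reference_on_random_matrix(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(60, 5)))
        out = ls.normalize_matrix(M)
        assert np.allclose(out.to_numpy(), self.reference_pipeline(M.to_numpy()))

    def test_identical_columns_stay_identical(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=40)
        M = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=40)})
        out = ls.normalize_matrix(M)
        assert np.allclose(out["a"], out["b"])

    def test_columns_share_sorted_vector_and_range(self):
        rng = np.random.default_rng(2)
        M = pd.DataFrame(rng.normal(size=(200, 6)))
        out = ls.normalize_matrix(M).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1000.0)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out1 = ls.normalize_matrix(M)
        out2 = ls.normalize_matrix(M[["d", "b", "a", "c"]])
        assert np.allclose(out1[["d", "b", "a", "c"]].to_numpy(), out2.to_numpy())

    def test_zero_variance_row_is_an_error(self):
        M = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            ls.normalize_matrix(M)

    def test_tied_values_get_mean_reference(self):
        # rows 0 and 1 are scaled copies, so column a holds tied z-scores
        M = pd.DataFrame([[1.0, 5.0, 3.0], [2.0, 10.0, 6.0], [4.0, 9.0, 2.0]],
                         columns=list("abc"))
        Z = ls.normalize_matrix(M)
        a = Z["a"].to_numpy()
        assert a[0] == a[1]


class TestVoomWeights:
    def make_counts(self, rng, n=200, sd=0.3, sd_slope=0.0):
        sheet = sheet_for(["c1", "c2", "c3"])
        base = rng.uniform(3, 9, size=n)  # mean log2 count
        sds = sd + sd_slope * (base - base.min()) / (base.max() - base.min())
        logc = base[:, None] + rng.normal(size=(n, 6)) * sds[:, None]
        M = pd.DataFrame(np.maximum(2 ** logc - 0.5, 0).round(),
                         columns=sheet.sample_ids)
        return M, sheet

    def test_homoskedastic_weights_nearly_constant(self):
        rng = np.random.default_rng(4)
        M, sheet = self.make_counts(rng, sd=0.3)
        W = ls.voom_weights(M, sheet)
        mid = W.to_numpy().mean()
        inner = W.to_numpy()[(M.to_numpy() > 2 ** 4) & (M.to_numpy() < 2 ** 8)]
        assert inner.std() / inner.mean() < 0.10

    def test_decreasing_variance_gives_increasing_weights(self):
        rng = np.random.default_rng(5)
        M, sheet = self.make_counts(rng, sd=0.8, sd_slope=-0.6)
        W = ls.voom_weights(M, sheet)
        mean_log = np.log2(M.to_numpy() + 0.5).mean(axis=1)
        lo = W.to_numpy()[mean_log < np.quantile(mean_log, 0.3)].mean()
        hi = W.to_numpy()[mean_log > np.quantile(mean_log, 0.7)].mean()
        assert hi > lo
        assert (W.to_numpy() > 0).all()

    def test_fallback_to_unit_weights_below_min_rows(self):
        rng = np.random.default_rng(6)
        M, sheet = self.make_counts(rng, n=20)
        with pytest.warns(UserWarning, match="unit weights"):
            W = ls.voom_weights(M, sheet)
        assert (W.to_numpy() == 1.0).all()


class TestVariability:
    def test_constant_row_not_significant_for_all_methods(self):
        sheet = sheet_for(["c1", "c2", "c3"])
        rng = np.random.default_rng(7)
        M = pd.DataFrame(rng.uniform(0, 1000, size=(30, 6)), columns=sheet.sample_ids)
        M.iloc[0] = 500.0
        for method in ("lmm_lrt", "lm_anova", "kruskal"):
            res = ls.test_variability(M, sheet, method=method)
            assert res.table["p"].iloc[0] > 0.9

    def test_planted_effect_detected_and_null_rows_not(self):
        sheet = sheet_for(["c1", "c2", "c3"])
        rng = np.random.default_rng(8)
        M = pd.DataFrame(rng.normal(100, 5, size=(300, 6)), columns=sheet.sample_ids)
        M.iloc[:20, 0:2] += 100  # strong effect in cell type c1
        M = M.clip(lower=0)
        for method in ("lmm_lrt", "lm_anova"):
            res = ls.test_variability(M, sheet, method=method, fdr=0.10)
            hit = res.table.index[:20].isin(res.variable_ids)
            assert hit.mean() > 0.9, method
            false = res.table.index[20:].isin(res.variable_ids)
            assert false.mean() < 0.05, method
        # the rank test cannot reach BH significance at n=6 (its p-values sit
        # on a discrete floor); planted rows must all reach that floor
        res = ls.test_variability(M, sheet, method="kruskal")
        p = res.table["p"]
        assert (p.iloc[:20] <= 0.2).all()  # near the discrete floor of ~0.10
        assert p.iloc[20:].median() > 0.3

    def test_lmm_lrt_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        sheet = sheet_for(["c1", "c2", "c3"], n_reps=4)
        rng = np.random.default_rng(9)
        n = 12
        eff = np.repeat(rng.normal(0, 1.0, 3), 4)
        y = 5 + eff + rng.normal(0, 0.5, n)
        M = pd.DataFrame([np.exp(y) - 1], columns=sheet.sample_ids)
        res = ls.test_variability(M, sheet, weights=None, method="lmm_lrt")
        df = pd.DataFrame({"y": np.log(M.iloc[0].to_numpy() + 1),
                           "g": [s.rsplit("_", 1)[0] for s in sheet.sample_ids]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=False)
            null = smf.ols("y ~ 1", df).fit()
        lrt_sm = 2 * (full.llf - null.llf)
        p_sm = stats.chi2.sf(lrt_sm, 1)
        assert res.table["p"].iloc[0] == pytest.approx(p_sm, abs=0.02)

    def test_boundary_mixture_halves_interior_p(self):
        sheet = sheet_for(["c1", "c2", "c3"])
        rng = np.random.default_rng(10)
        M = pd.DataFrame(rng.normal(100, 5, size=(20, 6)), columns=sheet.sample_ids)
        M.iloc[:, 0:2] += 50
        plain = ls.test_variability(M, sheet, method="lmm_lrt")
        mix = ls.test_variability(M, sheet, method="lmm_lrt", boundary_mixture=True)
        interior = plain.table["p"] < 0.5
        assert np.allclose(mix.table.loc[interior, "p"],
                           plain.table.loc[interior, "p"] / 2)

    def test_requires_replicates(self):
        sheet = sheet_for(["c1", "c2", "c3"], n_reps=1)
        M = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                         columns=sheet.sample_ids)
        with pytest.raises(ValueError, match="2 samples"):
            ls.test_variability(M, sheet)


class TestRelativeEntropy:
    def test_reference_values(self):
        assert ls.relative_entropy([3, 3, 3, 3]) == pytest.approx(0.0)
        assert ls.relative_entropy([1, 0, 0, 0]) == pytest.approx(2.0)
        assert ls.relative_entropy([0.5, 0.5, 0, 0]) == pytest.approx(1.0)

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = rng.uniform(0, 10, size=8)
            re = ls.relative_entropy(v)
            assert 0.0 <= re <= np.log2(8) + 1e-12
            assert ls.relative_entropy(v * 17.3) == pytest.approx(re)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            ls.relative_entropy([0, 0, 0])

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(12)
        M = pd.DataFrame(rng.uniform(0, 5, size=(20, 6)))
        rows = ls.relative_entropy_rows(M)
        for i in range(20):
            assert rows.iloc[i] == pytest.approx(ls.relative_entropy(M.iloc[i]))


class TestStaticSets:
    def test_uniform_loop_outranks_concentrated_loop(self):
        M = pd.DataFrame([[8, 8, 8, 8], [8, 0, 0, 0], [2, 2, 2, 2]],
                         index=["uniform_hi", "one_hot", "uniform_lo"],
                         columns=list("abcd"))
        chosen = ls.static_sets(M, variable_ids=["one_hot", "uniform_lo"])
        # RE=0 loops rank first, ordered by mean frequency descending
        assert list(chosen) == ["uniform_hi", "uniform_lo"]

    def test_output_size_matches_variable_set(self):
        rng = np.random.default_rng(13)
        M = pd.DataFrame(rng.poisson(10, size=(100, 6)) + 1.0)
        var = list(M.index[:17])
        assert len(ls.static_sets(M, var)) == 17

    def test_matched_mode_matches_strata_exactly(self):
        rng = np.random.default_rng(14)
        n = 500
        M = pd.DataFrame(rng.poisson(10, size=(n, 6)) + 1.0)
        spans = pd.Series(rng.integers(10_000, 5_000_000, size=n), index=M.index)
        loop_p = pd.Series(rng.uniform(size=n), index=M.index)
        q = pd.Series(rng.uniform(size=n), index=M.index)
        var = list(M.index[q < 0.05][:20])
        chosen = ls.static_sets(M, var, spans=spans, loop_p=loop_p, variability_q=q,
                                mode="matched", seed=0, n_deciles=4)
        assert len(chosen) == len(var)
        assert (q.loc[chosen] > 0.5).all()
        edges_s = pd.qcut(spans, 4, labels=False, duplicates="drop")
        edges_p = pd.qcut(loop_p.rank(method="first"), 4, labels=False, duplicates="drop")
        for ids in (var, list(chosen)):
            pass
        var_cells = list(zip(edges_s.loc[var], edges_p.loc[var]))
        ctrl_cells = list(zip(edges_s.loc[chosen], edges_p.loc[chosen]))
        assert sorted(var_cells) == sorted(ctrl_cells)

    def test_matched_mode_infeasible_raises(self):
        rng = np.random.default_rng(15)
        M = pd.DataFrame(rng.poisson(10, size=(30, 4)) + 1.0)
        spans = pd.Series(rng.integers(10_000, 100_000, size=30), index=M.index)
        loop_p = pd.Series(rng.uniform(size=30), index=M.index)
        q = pd.Series(0.1, index=M.index)  # no candidates with q > 0.5
        with pytest.raises(ValueError, match="infeasible"):
            ls.static_sets(M, list(M.index[:5]), spans=spans, loop_p=loop_p,
                           variability_q=q, mode="matched")


class TestGeneClasses:
    def test_uniform_and_one_cell_genes(self):
        rng = np.random.default_rng(16)
        expr = pd.DataFrame(rng.uniform(2, 20, size=(100, 6)),
                            index=[f"g{i}" for i in range(100)])
        expr.iloc[0] = 10.0                   # perfectly uniform, > 1 TPM
        expr.iloc[1] = 0.0
        expr.iloc[1, 2] = 40.0                # single-cell-type gene
        res = ls.classify_genes_entropy(expr, tail=0.10)
        assert "g0" in res["housekeeping"]
        assert "g1" in res["cell_type_specific"]
        assert len(res["housekeeping"]) == len(res["cell_type_specific"]) == 10
        assert len(set(res["housekeeping"]) & set(res["cell_type_specific"])) == 0

    def test_housekeeping_respects_min_expression(self):
        rng = np.random.default_rng(17)
        expr = pd.DataFrame(rng.uniform(5, 6, size=(50, 4)))
        expr.iloc[:10] = 0.5  # uniform but below 1 TPM everywhere
        res = ls.classify_genes_entropy(expr, min_expr_tpm=1.0, tail=0.10)
        assert not set(range(10)) & set(res["housekeeping"])

    def test_too_few_genes_is_an_error(self):
        expr = pd.DataFrame(np.ones((5, 4)) * 3.0)
        with pytest.raises(ValueError):
            ls.classify_genes_entropy(expr)


class TestSampleSimilarity:
    def test_duplicated_column_has_correlation_one(self):
        sheet = sheet_for(["c1", "c2", "c3"])
        rng = np.random.default_rng(18)
        M = pd.DataFrame(rng.poisson(20, size=(500, 6)).astype(float),
                         columns=sheet.sample_ids)
        M["c1_r2"] = M["c1_r1"]
        pairs, _ = ls.sample_similarity(M, sheet)
        row = pairs[(pairs["sample_1"] == "c1_r1") & (pairs["sample_2"] == "c1_r2")]
        assert row["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        sheet = sheet_for(["c1", "c2", "c3"])
        rng = np.random.default_rng(19)
        M = pd.DataFrame(rng.poisson(20, size=(5000, 6)).astype(float),
                         columns=sheet.sample_ids)
        pairs, _ = ls.sample_similarity(M, sheet)
        assert (pairs["spearman_rho"].abs() < 0.1).all()

    def test_replicates_correlate_above_cross_pairs(self, small_ds, small_norm):
        Mf, _ = small_norm
        pairs, comps = ls.sample_similarity(Mf, small_ds.sample_sheet)
        med_rep = pairs.loc[pairs["same_cell_type"], "spearman_rho"].median()
        med_all = pairs.loc[~pairs["same_cell_type"], "spearman_rho"].median()
        assert med_rep > med_all
        assert "p_bonferroni" in comps.columns


class TestPCA:
    def test_variance_fractions_valid(self, small_ds, small_norm):
        _, norm = small_norm
        res = ls.pca_and_confounders(norm, small_ds.sample_sheet, n_pcs=10)
        vf = res["variance_fraction"]
        assert (vf >= 0).all() and vf.sum() <= 1.0 + 1e-9

    def test_groups_recovered_on_first_two_pcs(self, small_ds, small_norm):
        _, norm = small_norm
        res = ls.pca_and_confounders(norm, small_ds.sample_sheet, n_pcs=3)
        emb = res["embedding"][["PC1", "PC2"]]
        group_of = small_ds.sample_sheet.group_of()
        labels = np.array([group_of[s] for s in emb.index])
        centroids = {g: emb[labels == g].mean(axis=0) for g in set(labels)}
        assigned = [
            min(centroids, key=lambda g: np.sum((emb.loc[s] - centroids[g]) ** 2))
            for s in emb.index
        ]
        assert (np.array(assigned) == labels).all()

    def test_random_batch_covariate_not_associated(self, small_ds, small_norm):
        _, norm = small_norm
        rng = np.random.default_rng(20)
        cov = pd.DataFrame({"random_batch": rng.choice(["x", "y"], size=norm.shape[1])},
                           index=norm.columns)
        res = ls.pca_and_confounders(norm, small_ds.sample_sheet,
                                     covariates=cov, n_pcs=5)
        assert (res["associations"]["q"] > 0.10).all()

    def test_constant_covariate_skipped(self, small_ds, small_norm):
        _, norm = small_norm
        cov = pd.DataFrame({"const": ["x"] * norm.shape[1]}, index=norm.columns)
        with pytest.warns(UserWarning, match="constant"):
            res = ls.pca_and_confounders(norm, small_ds.sample_sheet,
                                         covariates=cov, n_pcs=3)
        assert len(res["associations"]) == 0
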