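"""The five prognosis pipelines: selection rules, stacking contracts."""

import numpy as np
import pandas as pd
import pytest

from radfusion.fusion import (
    BenchmarkConfig,
    RFConfig,
    correlation_filter,
    fuse_pca,
    n_components_for_variance,
    riskscore_fit,
    riskscore_predict,
    run_benchmark,
    select_boruta,
    select_lasso,
)

def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestPCAComponents:
    def test_rank_two_matrix_needs_two_components(self, rng):
        base = rng.normal(size=(100, 2))
        x = frame(base @ rng.normal(size=(2, 6)))
        assert n_components_for_variance(x) == 2

    def test_duplicated_feature_needs_one(self, rng):
        col = rng.normal(size=100)
        x = frame(np.tile(col[:, None], (1, 10)))
        assert n_components_for_variance(x) == 1

    def test_iid_features_need_all_five(self, rng):
        x = frame(rng.normal(size=(1000, 5)))
        assert n_components_for_variance(x) == 5

    def test_component_count_minimal(self, rng):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler
        x = frame(rng.normal(size=(80, 12)) @ rng.normal(size=(12, 12)))
        k = n_components_for_variance(x, 0.95)
        cum = np.cumsum(PCA().fit(StandardScaler().fit_transform(x)).explained_variance_ratio_)
        assert cum[k - 1] >= 0.95 - 1e-12
        if k > 1:
            assert cum[k - 2] < 0.95

    def test_invalid_threshold_rejected(self, rng, small_cohort):
        bank_r, bank_t, df = small_cohort
        with pytest.raises(ValueError):
            fuse_pca(bank_r, bank_t, bank_r, bank_t, (df.label_2yr >= 1).astype(int),
                     var_threshold=1.5)


class TestCorrelationFilter:
    def test_duplicate_column_drops_exactly_one(self, rng):
        col = rng.normal(size=50)
        x = frame(np.column_stack([col, col, rng.normal(size=50)]))
        kept = correlation_filter(x)
        assert len(kept) == 2 and "f2" in kept

    def test_independent_features_untouched(self, rng):
        x = frame(rng.normal(size=(200, 6)))
        assert correlation_filter(x) == list(x.columns)

    def test_greedy_rule_never_removes_uncorrelated_feature(self, rng):
        # construct r12 ~ 0.9, r13 ~ 0.2, r23 ~ 0.3: feature 3 must survive
        g = np.random.default_rng(0)
        z = g.normal(size=2000)
        x1 = z + 0.45 * g.normal(size=2000)
        x2 = z + 0.45 * g.normal(size=2000)
        x3 = 0.25 * z + g.normal(size=2000)
        x = frame(np.column_stack([x1, x2, x3]))
        kept = correlation_filter(x, corr_cutoff=0.7)
        assert "f2" in kept and len(kept) == 2

    def test_survivors_below_cutoff(self, rng):
        z = rng.normal(size=(120, 3))
        x = frame(np.hstack([z[:, [j]] + 0.4 * rng.normal(size=(120, 4))
                             for j in range(3)]))
        kept = correlation_filter(x, corr_cutoff=0.7)
        r = np.abs(np.corrcoef(x[kept].to_numpy(), rowvar=False))
        np.fill_diagonal(r, 0.0)
        assert r.max() <= 0.7 + 1e-12


class TestSelectLasso:
    def test_recovers_predictive_features(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        signal = y + 0.3 * rng.normal(size=n)
        x = frame(np.column_stack([signal] + [rng.normal(size=n) for _ in range(8)]))
        selected = select_lasso(x, y, seed=0)
        assert "f0" in selected

    def test_empty_after_filter_impossible_with_distinct_columns(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        x = frame(rng.normal(size=(60, 5)))
        assert len(select_lasso(x, y, seed=1)) >= 1


class TestBoruta:
    def test_low_iteration_count_rejected(self, rng):
        x = frame(rng.normal(size=(30, 4)))
        with pytest.raises(ValueError):
            select_boruta(x, rng.integers(0, 2, 30), max_iter=0)

    def test_predictive_feature_confirmed_and_noise_contained(self):
        # On all-noise data the only admissible confirmation is the single
        # feature with the luckiest in-sample association: at n = 200 the
        # best of 21 noise columns reaches |r| ~ 0.2, which is genuinely
        # in-sample relevant by the all-relevant criterion.  More than one
        # confirmation, or confirmation of a mid-ranked column, would
        # indicate a broken null envelope.
        confirmed_hits, contained = 0, 0
        for seed in range(5):
            g = np.random.default_rng(seed)
            y = g.integers(0, 2, 200)
            signal = y + 0.4 * g.normal(size=200)
            x = frame(np.column_stack([signal] + [g.normal(size=200) for _ in range(20)]))
            sel = select_boruta(x, y, max_iter=20, seed=seed, n_trees=100)
            confirmed_hits += "f0" in sel
            noise = frame(g.normal(size=(200, 21)))
            null_sel = select_boruta(noise, y, max_iter=20, seed=seed, n_trees=100)
            if len(null_sel) <= 1:
                corr = noise.apply(lambda c: abs(np.corrcoef(c, y)[0, 1]))
                top3 = set(corr.nlargest(3).index)
                contained += (not null_sel) or (null_sel[0] in top3)
        assert confirmed_hits >= 4
        assert contained >= 4


class TestRiskScore:
    @pytest.fixture(scope="class")
    def separable(self):
        g = np.random.default_rng(0)
        y = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
        g.shuffle(y)
        r = frame(np.column_stack([y + 0.01 * g.normal(size=60) for _ in range(4)]), "r")
        t = frame(np.column_stack([y + 0.01 * g.normal(size=60) for _ in range(3)]), "t")
        return r, t, y

    def test_fold_bounds_validated(self, separable):
        r, t, y = separable
        with pytest.raises(ValueError):
            riskscore_fit(r, t, y, folds=1)
        with pytest.raises(ValueError):
            riskscore_fit(r, t, y, folds=40)

    def test_perfectly_predictive_banks_reach_auc_one(self, separable):
        from radfusion.evaluation import roc_auc
        r, t, y = separable
        bundle = riskscore_fit(r, t, y, folds=5, rf=RFConfig(n_trees=100, mtry=2),
                               seed=0)
        scores = riskscore_predict(bundle, r, t)
        assert roc_auc(scores, y) == pytest.approx(1.0)

    def test_out_of_fold_bookkeeping(self, separable):
        r, t, y = separable
        bundle = riskscore_fit(r, t, y, folds=5, rf=RFConfig(n_trees=50, mtry=2), seed=1)
        pairs = bundle.train_pairs
        assert pairs.shape[0] == 60
        assert pairs[["p_bankR", "p_bankT"]].to_numpy().min() >= 0.0
        assert pairs[["p_bankR", "p_bankT"]].to_numpy().max() <= 1.0
        assert set(pairs.fold_id.astype(int)) == set(range(5))
        # stratification: every fold holds out both classes
        for k, sub in pairs.groupby("fold_id"):
            held = y[[pairs.index.get_loc(i) for i in sub.index]]
            assert len(np.unique(held)) == 2

    def test_column_mismatch_named_in_error(self, separable):
        r, t, y = separable
        bundle = riskscore_fit(r, t, y, folds=5, rf=RFConfig(n_trees=50, mtry=2), seed=2)
        bad = r.rename(columns={"r0": "rogue"})
        with pytest.raises(ValueError, match="rogue"):
            riskscore_predict(bundle, bad, t)

    def test_permuting_test_rows_permutes_predictions(self, separable):
        r, t, y = separable
        bundle = riskscore_fit(r, t, y, folds=5, rf=RFConfig(n_trees=50, mtry=2), seed=3)
        scores = riskscore_predict(bundle, r, t)
        perm = np.random.default_rng(4).permutation(len(y))
        permuted = riskscore_predict(bundle, r.iloc[perm], t.iloc[perm])
        assert np.allclose(permuted, scores[perm])


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        from radfusion.synthetic import study_cohorts
        tr_r, tr_t, tr_df, te_r, te_t, te_df = study_cohorts(
            3, n_train=40, n_test=20, n_features_bankR=60)
        config = BenchmarkConfig(seed=3, n_trees=60, folds=5,
                                 boruta_max_iter=8, boruta_n_trees=60)
        return tr_r, tr_t, tr_df, te_r, te_t, te_df, config

    def test_deterministic_and_complete(self, tiny_setup):
        tr_r, tr_t, tr_df, te_r, te_t, te_df, config = tiny_setup
        res1 = run_benchmark(tr_r, tr_t, te_r, te_t, tr_df,
                             te_df.label_2yr.to_numpy(), config)
        res2 = run_benchmark(tr_r, tr_t, te_r, te_t, tr_df,
                             te_df.label_2yr.to_numpy(), config)
        assert res1.table.equals(res2.table)
        assert list(res1.table.index) == ["pca", "boruta", "cox", "lasso", "riskscore"]
        assert res1.table["auc"].between(0, 1).all()
        assert res1.table.loc["pca", "fdr_adjusted_p"] >= res1.table.loc["pca", "delong_p_vs_riskscore"] - 1e-12
        assert res1.single_bank_auc is not None
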