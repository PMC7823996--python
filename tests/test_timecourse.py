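"""PCA, PLS-on-time, loading ranking and the spline time-trend LRT."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import metabodyn as md

from conftest import make_table


def _timecourse_table(values, n_replicates=3):
    return make_table(np.asarray(values, dtype=float), n_replicates=n_replicates)


class TestPCA:
    def test_rank_one_table_concentrates_variance(self):
        profile = np.linspace(1, 4, 6)
        vals = np.outer([1.0, 2.0, 5.0], profile) ** 2  # sqrt makes it rank 1
        res = md.pca(_timecourse_table(vals, n_replicates=1))
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sums_to_one(self, design):
        table, _ = md.generate_feature_table(design, n_features=40, seed=3)
        res = md.pca(table.drop_blanks())
        assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_intensity_rejected(self):
        table = _timecourse_table(np.array([[-1.0, 2.0, 1.0]]), n_replicates=1)
        with pytest.raises(ValueError):
            md.pca(table)

    def test_scores_track_time_on_trended_data(self, design):
        from scipy.stats import spearmanr

        table, _ = md.generate_feature_table(
            design, n_features=200, frac_trend=0.5, noise_cv=0.1, seed=7
        )
        cells = table.drop_blanks()
        res = md.pca(cells)
        first48 = cells.sample_meta["time_h"] <= 48
        rho = spearmanr(res.scores.loc[first48.values, "PC1"],
                        cells.sample_meta.loc[first48, "time_h"])[0]
        assert abs(rho) > 0.8

    def test_duplicated_sample_keeps_rank_one_loading_direction(self):
        profile = np.linspace(1, 4, 6) ** 2
        vals = np.outer([1.0, 2.0, 5.0], profile)
        t1 = _timecourse_table(vals, n_replicates=1)
        vals_dup = np.column_stack([vals, vals[:, -1]])
        t2 = make_table(vals_dup, time_points=[0, 12, 24, 36, 48, 60, 60],
                        n_replicates=1)
        l1 = md.pca(t1).loadings["PC1"].to_numpy()
        l2 = md.pca(t2).loadings["PC1"].to_numpy()
        cos = abs(l1 @ l2) / (np.linalg.norm(l1) * np.linalg.norm(l2))
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestPLS:
    def test_single_linear_feature_dominates_loading(self):
        n_t = 9
        rng = np.random.default_rng(0)
        flat = np.exp(rng.normal(5, 0.001, size=(10, n_t)))
        linear = np.exp(np.linspace(4, 8, n_t))[None, :]
        table = _timecourse_table(np.vstack([linear, flat]), n_replicates=1)
        res = md.pls_time(table, n_components=1)
        load = res.loadings["PLS1"].abs()
        assert load.idxmax() == table.values.index[0]

    def test_constant_time_rejected(self):
        vals = np.ones((3, 4))
        table = make_table(vals, time_points=[0, 0, 0, 0], n_replicates=1)
        with pytest.raises(ValueError, match="constant"):
            md.pls_time(table)

    def test_zero_intensity_requires_offset(self):
        vals = np.array([[0.0, 1.0, 2.0]])
        table = _timecourse_table(vals, n_replicates=1)
        res = md.pls_time(table)  # auto +1 offset for zeros
        assert res.scores.shape[1] >= 1
        with pytest.raises(ValueError):
            md.pls_time(table.with_values(table.values - 1.0))

    def test_matches_sklearn_nipals(self, design):
        table, _ = md.generate_feature_table(
            design, n_features=30, frac_trend=0.5, noise_cv=0.1, seed=4
        )
        cells = table.drop_blanks()
        ours = md.pls_time(cells, n_components=2)
        x = np.log(cells.values.to_numpy().T)
        y = cells.sample_meta["time_h"].to_numpy(dtype=float)
        ref = PLSRegression(n_components=2, scale=False).fit(x, y)
        for k in range(2):
            a = ours.scores.iloc[:, k].to_numpy()
            b = ref.x_scores_[:, k]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_deterministic(self, design):
        table, _ = md.generate_feature_table(design, n_features=30, seed=4)
        cells = table.drop_blanks()
        r1 = md.pls_time(cells)
        r2 = md.pls_time(cells)
        assert r1.scores.equals(r2.scores) and r1.loadings.equals(r2.loadings)

    def test_sign_convention_scores_rise_with_time(self, design):
        table, _ = md.generate_feature_table(
            design, n_features=100, frac_trend=0.5, seed=9
        )
        cells = table.drop_blanks()
        res = md.pls_time(cells)
        t = cells.sample_meta["time_h"]
        s = res.scores["PLS1"]
        assert s[t == 96].mean() >= s[t == 0].mean()


class TestLoadingRanking:
    def test_sum_of_absolute_loadings(self):
        loadings = pd.DataFrame(
            {"PLS1": [0.9, 0.2], "PLS2": [-0.1, 0.2]}, index=["a", "b"]
        )
        res = md.OrdinationResult(
            scores=pd.DataFrame(), loadings=loadings,
            explained_variance=np.array([]), scaling="log", method="pls",
        )
        ranked = md.rank_features_by_loading(res)
        assert list(ranked.index) == ["a", "b"]
        assert ranked["importance"].tolist() == pytest.approx([1.0, 0.4])

    def test_all_zero_ties_break_by_id(self):
        loadings = pd.DataFrame({"PLS1": [0.0, 0.0, 0.0]}, index=["c", "a", "b"])
        res = md.OrdinationResult(
            scores=pd.DataFrame(), loadings=loadings,
            explained_variance=np.array([]), scaling="log", method="pls",
        )
        assert list(md.rank_features_by_loading(res).index) == ["a", "b", "c"]

    def test_trended_features_fill_top_decile(self, design):
        table, truth = md.generate_feature_table(
            design, n_features=300, frac_trend=0.5, noise_cv=0.1, seed=7
        )
        ranked = md.rank_features_by_loading(md.pls_time(table.drop_blanks()))
        top = ranked.index[:30]
        trended = set(truth.trended_feature_ids)
        assert sum(f in trended for f in top) / 30 >= 0.8


class TestTimeTrendLRT:
    def test_constant_feature_not_significant(self):
        vals = np.tile(7.0, (1, 27))
        table = make_table(vals, n_replicates=3)
        res = md.time_trend_lrt(table)
        assert res.per_feature["lrt_stat"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not bool(res.significant.iloc[0])

    def test_statistic_non_negative(self, design):
        table, _ = md.generate_feature_table(design, n_features=100, seed=17)
        res = md.time_trend_lrt(table)
        assert (res.per_feature["lrt_stat"] >= 0).all()

    def test_strong_trend_detected(self, design):
        table, truth = md.generate_feature_table(
            design, n_features=60, frac_trend=0.5, noise_cv=0.05, seed=5
        )
        res = md.time_trend_lrt(table.drop_blanks())
        trended = set(truth.trended_feature_ids)
        sig = set(res.significant[res.significant].index)
        assert len(trended & sig) / len(trended) >= 0.9

    def test_spline_df_must_be_below_time_points(self, design):
        table, _ = md.generate_feature_table(design, n_features=5, seed=1)
        with pytest.raises(ValueError, match="spline_df"):
            md.time_trend_lrt(table, spline_df=9)

    def test_bonferroni_implies_raw_significance(self, design):
        table, _ = md.generate_feature_table(
            design, n_features=50, frac_trend=0.5, seed=2
        )
        res = md.time_trend_lrt(table.drop_blanks())
        sig = res.per_feature[res.per_feature["significant"]]
        assert (sig["p"] < res.alpha / res.n_tested).all()

    def test_chisq_reference_available_and_anticonservative(self, design):
        table, _ = md.generate_feature_table(
            design, n_features=200, frac_trend=0.0, noise_cv=0.1, seed=3
        )
        p_f = md.time_trend_lrt(table, reference="f").per_feature["p"]
        p_chi = md.time_trend_lrt(table, reference="chisq").per_feature["p"]
        assert (p_chi <= p_f + 1e-12).all()
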