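"""PCA, loading clustering, outcome correlations, and PLS-DA with VIP."""

import numpy as np
import pandas as pd
import pytest

import thyromet as tm
from thyromet.errors import InvalidArgumentError
from thyromet.multivariate import PCAResult, heatmap_order

from conftest import make_table


def pareto_of(raw_values):
    out, _ = tm.pareto_scale(tm.log_transform(make_table(raw_values)))
    return out


class TestPCA:
    def test_collinear_data_single_component(self, rng):
        t = rng.normal(0, 1, 12)
        vals = np.column_stack([t, 2 * t, -0.5 * t])
        table = tm.FeatureTable(values=pd.DataFrame(vals), stage="pareto")
        res = tm.pca(table)
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert res.explained_ratio[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_explained_ratios_sum_to_one(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (10, 6))))
        res = tm.pca(table)
        assert res.explained_ratio.sum() == pytest.approx(1.0, rel=1e-12)
        assert (np.diff(res.explained_ratio) <= 1e-12).all()

    def test_matches_covariance_eigenvalues(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (10, 6))))
        res = tm.pca(table)
        x = table.values.to_numpy()
        xc = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        np.testing.assert_allclose(
            res.explained_ratio, evals[: len(res.explained_ratio)] / evals.sum(),
            rtol=1e-9, atol=1e-12,
        )

    def test_scores_centered_with_diagonal_covariance(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (12, 5))))
        s = tm.pca(table).scores.to_numpy()
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-10)
        cov = s.T @ s
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.diag(cov).max()

    def test_loadings_orthonormal(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (9, 7))))
        L = tm.pca(table).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (9, 7))))
        L = tm.pca(table).loadings.to_numpy()
        for c in range(L.shape[1]):
            assert L[np.abs(L[:, c]).argmax(), c] > 0

    def test_all_zero_matrix_rejected(self):
        table = tm.FeatureTable(values=pd.DataFrame(np.zeros((4, 3))), stage="pareto")
        with pytest.raises(InvalidArgumentError):
            tm.pca(table)


class TestComponentsForVariance:
    def test_known_ratios(self):
        res = PCAResult(
            loadings=pd.DataFrame(np.eye(3)),
            scores=pd.DataFrame(np.zeros((3, 3))),
            explained_ratio=np.array([0.6, 0.3, 0.1]),
        )
        assert tm.n_components_for_variance(res, 0.9) == 2
        assert tm.n_components_for_variance(res, 0.95) == 3
        assert tm.n_components_for_variance(res, 1.0) == 3

    def test_agrees_with_cumulative_scan(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (15, 10))))
        res = tm.pca(table)
        for frac in (0.5, 0.8, 0.9, 0.99):
            m = tm.n_components_for_variance(res, frac)
            cum = np.cumsum(res.explained_ratio)
            assert cum[m - 1] >= frac - 1e-9
            assert m == 1 or cum[m - 2] < frac


class TestLoadingClusters:
    def test_orthogonal_blocks_recovered(self, rng):
        t1, t2 = rng.normal(0, 1, (12, 1)), rng.normal(0, 1, (12, 1))
        vals = np.hstack([np.tile(t1, 4) + rng.normal(0, 0.05, (12, 4)),
                          np.tile(t2, 4) + rng.normal(0, 0.05, (12, 4))])
        table = tm.FeatureTable(values=pd.DataFrame(vals), stage="pareto")
        res = tm.pca(table)
        clusters = tm.cluster_loadings(res, n_pcs=2, k=2)
        assert clusters.iloc[:4].nunique() == 1
        assert clusters.iloc[4:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[4]

    def test_k_equals_features_gives_singletons(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (8, 5))))
        res = tm.pca(table)
        assert tm.cluster_loadings(res, n_pcs=3, k=5).nunique() == 5

    def test_k_out_of_range(self, rng):
        table = pareto_of(np.exp(rng.normal(3, 0.5, (8, 5))))
        res = tm.pca(table)
        with pytest.raises(InvalidArgumentError):
            tm.cluster_loadings(res, n_pcs=2, k=1)


class TestOutcomeCorrelations:
    def make_cohort(self, y):
        return [tm.SampleInfo(f"S{i}", int(v), 50.0) for i, v in enumerate(y)]

    def test_indicator_feature_has_unit_correlation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        table = tm.FeatureTable(
            values=pd.DataFrame({"F0": y.astype(float)},
                                index=[f"S{i}" for i in range(6)]),
            stage="pareto",
        )
        r = tm.feature_outcome_correlations(table, self.make_cohort(y))
        assert r["F0"] == pytest.approx(1.0)

    def test_matches_scipy_pointbiserial(self, rng):
        y = np.array([0] * 10 + [1] * 8)
        vals = rng.normal(0, 1, (18, 5))
        table = tm.FeatureTable(
            values=pd.DataFrame(vals, index=[f"S{i}" for i in range(18)]),
            stage="pareto",
        )
        r = tm.feature_outcome_correlations(table, self.make_cohort(y))
        from scipy.stats import pointbiserialr

        for j in range(5):
            assert r.iloc[j] == pytest.approx(
                pointbiserialr(y, vals[:, j]).statistic, rel=1e-9
            )

    def test_heatmap_order_descends_within_cluster(self, rng):
        clusters = pd.Series([1, 1, 1, 2, 2], index=[f"F{j}" for j in range(5)])
        r = pd.Series(rng.uniform(-1, 1, 5), index=clusters.index)
        out = heatmap_order(clusters, r)
        for c, grp in out.groupby("cluster"):
            assert (np.diff(grp["r"].to_numpy()) <= 1e-12).all()


class TestPLSDA:
    def make_cohort(self, y):
        return [tm.SampleInfo(f"S{i}", int(v), 50.0) for i, v in enumerate(y)]

    def test_single_feature_equal_to_response(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        table = tm.FeatureTable(
            values=pd.DataFrame({"F0": y.astype(float)},
                                index=[f"S{i}" for i in range(6)]),
            stage="pareto",
        )
        res = tm.plsda(table, self.make_cohort(y), n_lv=1)
        assert res.y_var_pct[0] == pytest.approx(100.0, rel=1e-9)
        assert res.vip["F0"] == pytest.approx(1.0, rel=1e-9)

    def test_mean_squared_vip_is_one(self, study_cohort):
        table, _ = tm.generate_metabolome(study_cohort, 50, seed=12)
        par, _ = tm.pareto_scale(tm.log_transform(table))
        res = tm.plsda(par, study_cohort, n_lv=3)
        assert (res.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_scores_mutually_orthogonal(self, study_cohort):
        table, _ = tm.generate_metabolome(study_cohort, 30, seed=13)
        par, _ = tm.pareto_scale(tm.log_transform(table))
        T = tm.plsda(par, study_cohort, n_lv=4).scores.to_numpy()
        g = T.T @ T
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8 * np.diag(g).max()

    def test_y_variance_percentages_valid(self, study_cohort):
        table, _ = tm.generate_metabolome(
            study_cohort, 40, effects=[(j, 1.0) for j in range(8)], seed=14
        )
        par, _ = tm.pareto_scale(tm.log_transform(table))
        res = tm.plsda(par, study_cohort, n_lv=3)
        assert (res.y_var_pct >= 0).all()
        assert res.y_var_pct.sum() <= 100 + 1e-9
        assert (res.x_var_pct >= 0).all()

    def test_matches_sklearn_nipals_first_component(self, study_cohort):
        from sklearn.cross_decomposition import PLSRegression

        table, _ = tm.generate_metabolome(study_cohort, 20, seed=15)
        par, _ = tm.pareto_scale(tm.log_transform(table))
        res = tm.plsda(par, study_cohort, n_lv=2)
        y = np.array([s.group for s in study_cohort], dtype=float)
        ref = PLSRegression(n_components=2, scale=False).fit(
            par.values.to_numpy(), y
        )
        for c in range(2):
            w_ref = ref.x_weights_[:, c]
            w_got = res.weights.iloc[:, c].to_numpy()
            assert abs(abs(w_ref @ w_got) - 1.0) < 1e-8

    def test_informative_features_get_higher_vip(self, study_cohort):
        wins = 0
        for rep in range(50):
            table, _ = tm.generate_metabolome(
                study_cohort, 200, effects=[(j, 1.0) for j in range(10)],
                seed=600 + rep,
            )
            par, _ = tm.pareto_scale(tm.log_transform(table))
            vip = tm.plsda(par, study_cohort, n_lv=2).vip
            wins += vip.iloc[:10].mean() > vip.iloc[10:].mean()
        assert wins >= 48  # >= 95% of 50 replicates

    def test_zero_response_variance_rejected(self):
        table = tm.FeatureTable(
            values=pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)),
                                index=[f"S{i}" for i in range(4)]),
            stage="pareto",
        )
        cohort = [tm.SampleInfo(f"S{i}", 0, 50.0) for i in range(4)]
        with pytest.raises(InvalidArgumentError):
            tm.plsda(table, cohort, n_lv=1)
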