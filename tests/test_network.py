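"""Weighted sub-network construction, module detection, and outcome association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyromet as tm
from thyromet.errors import InvalidArgumentError

from conftest import make_table


def pareto_table(values, **kw):
    table = make_table(values, **kw)
    logt = tm.log_transform(table)
    out, _ = tm.pareto_scale(logt)
    return out


def random_adjacency(rng, n):
    a = rng.uniform(-1, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    ids = [f"F{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


def tom_direct(u):
    """Independent direct-summation TOM oracle (explicit loops)."""
    n = u.shape[0]
    k = u.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(u[i, l] * u[l, j] for l in range(n) if l not in (i, j))
            tom[i, j] = (shared + u[i, j]) / (min(k[i], k[j]) + 1 - u[i, j])
    return tom


class TestCorrelation:
    def test_unit_diagonal_and_sign_flip(self, rng):
        x = rng.normal(0, 1, (10, 1))
        table = tm.FeatureTable(
            values=pd.DataFrame(np.hstack([x, -x]), columns=["f", "neg"]),
            stage="pareto",
        )
        r = tm.correlation_matrix(table)
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert r.iloc[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_pairwise_pearson_oracle(self, rng):
        from scipy.stats import pearsonr

        table = pareto_table(np.exp(rng.normal(2, 0.5, (5, 4))))
        r = tm.correlation_matrix(table)
        x = table.values.to_numpy()
        for i in range(4):
            for j in range(4):
                want = pearsonr(x[:, i], x[:, j]).statistic if i != j else 1.0
                assert r.iloc[i, j] == pytest.approx(want, abs=1e-10)


class TestAdjacency:
    @pytest.mark.parametrize(
        "r,beta,tau,expected",
        [
            (1.0, 6.0, 0.1, 1.0),
            (-0.5, 2.0, 0.1, -0.25),
            (0.05, 6.0, 0.1, 0.0),
        ],
    )
    def test_signed_power_with_threshold(self, r, beta, tau, expected):
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        a = tm.signed_power_adjacency(rm, beta=beta, tau=tau)
        assert a.loc["a", "b"] == pytest.approx(expected, rel=1e-12)
        assert a.loc["a", "a"] == 0.0

    def test_invalid_parameters(self):
        rm = pd.DataFrame(np.eye(2))
        with pytest.raises(InvalidArgumentError):
            tm.signed_power_adjacency(rm, beta=0)
        with pytest.raises(InvalidArgumentError):
            tm.signed_power_adjacency(rm, tau=1.0)


class TestTOM:
    def test_perfect_overlap_two_nodes(self):
        a = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        tom, diss = tm.tom_dissimilarity(a)
        assert tom.loc["a", "b"] == pytest.approx(1.0)
        assert diss.loc["a", "b"] == pytest.approx(0.0)

    def test_all_zero_adjacency(self):
        a = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        tom, diss = tm.tom_dissimilarity(a)
        off = ~np.eye(3, dtype=bool)
        assert (tom.to_numpy()[off] == 0).all()
        assert (diss.to_numpy()[off] == 1).all()
        assert (np.diag(diss.to_numpy()) == 0).all()

    def test_three_node_hand_value(self):
        # u12 = u13 = 0.5, u23 = 0: tom_23 = 0.25 / 1.5 = 1/6
        u = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        a = pd.DataFrame(u, index=list("abc"), columns=list("abc"))
        tom, _ = tm.tom_dissimilarity(a)
        assert tom.loc["b", "c"] == pytest.approx(1 / 6, rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 6))
    def test_matches_direct_summation_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        a = random_adjacency(rng, n)
        tom, _ = tm.tom_dissimilarity(a)
        want = tom_direct(np.abs(a.to_numpy()))
        np.testing.assert_allclose(tom.to_numpy(), want, atol=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 12))
    def test_tom_bounded_in_unit_interval(self, seed, n):
        rng = np.random.default_rng(seed)
        tom, diss = tm.tom_dissimilarity(random_adjacency(rng, n))
        assert (tom.to_numpy() >= -1e-12).all() and (tom.to_numpy() <= 1 + 1e-12).all()
        assert (diss.to_numpy() >= -1e-12).all() and (diss.to_numpy() <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(InvalidArgumentError):
            tm.tom_dissimilarity(a)


class TestModules:
    def test_two_separated_blocks_recovered(self):
        n = 6
        d = np.ones((n, n))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        ids = [f"F{i}" for i in range(n)]
        labels = tm.cluster_modules(pd.DataFrame(d, index=ids, columns=ids), k=2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_k_equal_to_features_gives_singletons(self, rng):
        a = random_adjacency(rng, 5)
        _, diss = tm.tom_dissimilarity(a)
        labels = tm.cluster_modules(diss, k=5)
        assert labels.nunique() == 5

    def test_labels_ordered_by_decreasing_size(self, study_cohort):
        table, _ = tm.generate_metabolome(
            study_cohort, 60, modules=[(30, 0.8), (20, 0.8), (10, 0.8)], seed=4
        )
        par, _ = tm.pareto_scale(tm.log_transform(table))
        net = tm.build_network(par)
        labels = tm.cluster_modules(net.diss, k=3)
        sizes = labels.value_counts().sort_index()
        assert list(sizes.index) == [1, 2, 3]
        assert list(sizes.to_numpy()) == sorted(sizes.to_numpy(), reverse=True)

    def test_k_out_of_range(self, rng):
        _, diss = tm.tom_dissimilarity(random_adjacency(rng, 4))
        with pytest.raises(InvalidArgumentError):
            tm.cluster_modules(diss, k=1)
        with pytest.raises(InvalidArgumentError):
            tm.cluster_modules(diss, k=5)


class TestEigenmetabolites:
    def test_duplicated_feature_module(self, rng):
        x = np.exp(rng.normal(2, 0.3, (12, 1)))
        table = pareto_table(np.hstack([x, x]))
        labels = pd.Series([1, 1], index=table.feature_ids)
        mods = tm.eigenmetabolites(table, labels)
        assert mods.var_explained[1] == pytest.approx(1.0, abs=1e-9)
        col = table.values.iloc[:, 0].to_numpy()
        score = mods.eigenmetabolite[1].to_numpy()
        r = np.corrcoef(score, col)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_negating_members_leaves_oriented_score_unchanged(self, rng):
        vals = rng.normal(0, 1, (15, 6))
        ids = [f"F{j}" for j in range(6)]
        t1 = tm.FeatureTable(
            values=pd.DataFrame(vals, columns=ids), stage="pareto"
        )
        t2 = tm.FeatureTable(
            values=pd.DataFrame(-vals, columns=ids), stage="pareto"
        )
        labels = pd.Series(1, index=ids)
        m1 = tm.eigenmetabolites(t1, labels)
        m2 = tm.eigenmetabolites(t2, labels)
        np.testing.assert_allclose(
            np.abs(m1.eigenmetabolite[1].to_numpy()),
            np.abs(m2.eigenmetabolite[1].to_numpy()),
            atol=1e-9,
        )
        # both oriented positively toward their own members
        for m, t in ((m1, t1), (m2, t2)):
            cors = np.corrcoef(
                np.column_stack([m.eigenmetabolite[1], t.values.to_numpy()]),
                rowvar=False,
            )[0, 1:]
            assert cors.mean() > 0

    def test_matches_brute_force_eigendecomposition(self, rng):
        vals = rng.normal(0, 1, (35, 10))
        ids = [f"F{j}" for j in range(10)]
        table = tm.FeatureTable(values=pd.DataFrame(vals, columns=ids), stage="pareto")
        mods = tm.eigenmetabolites(table, pd.Series(1, index=ids))
        xc = vals - vals.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        v1 = evecs[:, -1]
        score = xc @ v1
        score /= np.linalg.norm(score)
        got = mods.eigenmetabolite[1].to_numpy()
        assert abs(abs(score @ got) - 1.0) < 1e-9
        assert mods.var_explained[1] == pytest.approx(
            evals[-1] / evals.sum(), rel=1e-9
        )

    def test_single_feature_module_warns(self, rng):
        vals = np.exp(rng.normal(1, 0.2, (8, 2)))
        table = pareto_table(vals)
        labels = pd.Series([1, 2], index=table.feature_ids)
        with pytest.warns(UserWarning, match="single feature"):
            mods = tm.eigenmetabolites(table, labels)
        assert mods.singleton_modules == [1, 2]


class TestAssociation:
    def make_modules(self, scores, sample_ids):
        em = pd.DataFrame({1: scores}, index=sample_ids)
        return tm.ModuleSet(
            labels=pd.Series(dtype=int),
            eigenmetabolite=em,
            var_explained={1: 1.0},
            orientation_sign={1: 1},
        )

    def test_perfect_separation_flagged(self):
        cohort = [tm.SampleInfo(f"S{i}", int(i >= 2), 50.0) for i in range(4)]
        mods = self.make_modules([-1.0, -1.0, 1.0, 1.0], [s.sample_id for s in cohort])
        with pytest.warns(UserWarning, match="separated"):
            assoc = tm.module_outcome_association(mods, cohort)
        assert assoc[0].separated
        assert assoc[0].ci95[1] == np.inf

    def test_logistic_recovers_known_coefficient(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        cohort = [tm.SampleInfo(f"S{i}", int(y[i]), 50.0) for i in range(n)]
        mods = self.make_modules(x, [s.sample_id for s in cohort])
        assoc = tm.module_outcome_association(mods, cohort)[0]
        # x already has unit variance (asymptotically), so coef ~ 1
        assert assoc.logit_coef == pytest.approx(1.0, abs=0.2)
        assert assoc.ci95[0] < assoc.or_ < assoc.ci95[1]
        assert (assoc.or_ > 1) == (assoc.logit_coef > 0)

    def test_pearson_matches_point_biserial(self, rng):
        x = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(int)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        cohort = [tm.SampleInfo(f"S{i}", int(y[i]), 50.0) for i in range(30)]
        mods = self.make_modules(x, [s.sample_id for s in cohort])
        assoc = tm.module_outcome_association(mods, cohort)[0]
        from scipy.stats import pearsonr

        want = pearsonr(x, y.astype(float))
        assert assoc.pearson_r == pytest.approx(want.statistic, rel=1e-9)
        assert assoc.pearson_p == pytest.approx(want.pvalue, rel=1e-9)


class TestPipelineEquivariance:
    def test_feature_permutation_permutes_labels(self, study_cohort):
        table, _ = tm.generate_metabolome(
            study_cohort, 40, modules=[(20, 0.8), (20, 0.8)], seed=9
        )
        par, _ = tm.pareto_scale(tm.log_transform(table))
        net = tm.build_network(par)
        labels = tm.cluster_modules(net.diss, k=2)

        rng = np.random.default_rng(0)
        perm = rng.permutation(par.values.columns)
        shuffled = tm.FeatureTable(values=par.values.loc[:, perm], stage="pareto")
        net2 = tm.build_network(shuffled)
        labels2 = tm.cluster_modules(net2.diss, k=2)
        # same partition of feature ids (module numbering may swap)
        from sklearn.metrics import adjusted_rand_score

        common = labels.index
        ari = adjusted_rand_score(labels.loc[common], labels2.loc[common])
        assert ari == pytest.approx(1.0)

    def test_high_beta_zero_tau_converges_to_near_one_components(self):
        # two |r| ~ 1 blocks: with large beta and tau = 0, only the
        # near-perfect correlations survive and modules equal the components
        rng = np.random.default_rng(1)
        base1 = rng.normal(0, 1, (30, 1))
        base2 = rng.normal(0, 1, (30, 1))
        vals = np.exp(
            np.hstack(
                [
                    base1 + rng.normal(0, 0.01, (30, 2)),
                    base2 + rng.normal(0, 0.01, (30, 2)),
                ]
            )
        )
        par = pareto_table(vals)
        net = tm.build_network(par, beta=30.0, tau=0.0)
        labels = tm.cluster_modules(net.diss, k=2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[0] != labels.iloc[2]
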