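import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from pyrograss.phylo_models import (
    PGLS,
    LeafTraitPCA,
    PhyloLogisticRegression,
    classify_strategy,
    leaf_trait_pca,
    load_tree,
    pgls_fit,
    tree_matrices,
)
from pyrograss.synthetic_data import simulate_binary_trait, simulate_phylogeny


def firth_logistic_oracle(X, y):
    """Independent oracle: directly maximize l(b) + 0.5 log|X'WX|."""
    Xd = np.column_stack([np.ones(len(y)), X])

    def negpen(b):
        mu = np.clip(expit(Xd @ b), 1e-12, 1 - 1e-12)
        ll = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        _, logdet = np.linalg.slogdet(Xd.T @ (Xd * (mu * (1 - mu))[:, None]))
        return -(ll + 0.5 * logdet)

    res = minimize(
        negpen, np.zeros(Xd.shape[1]), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    return res.x


class TestClassifyStrategy:
    @pytest.mark.parametrize(
        "mortality, expected", [(25.0, 1), (80.0, 0), (50.0, None), (29.9, 1), (70.1, 0)]
    )
    def test_rule(self, mortality, expected):
        assert classify_strategy(mortality) == expected

    @pytest.mark.parametrize("bad", [-1.0, 101.0])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_strategy(bad)


class TestTreeMatrices:
    def test_small_tree_by_hand(self):
        tree = load_tree("((A:1,B:1):2,C:3);")
        vcv, div, height = tree_matrices(tree, ["A", "B", "C"])
        np.testing.assert_allclose(vcv, [[3, 2, 0], [2, 3, 0], [0, 0, 3]])
        np.testing.assert_allclose(div, [[0, 1, 3], [1, 0, 3], [3, 3, 0]])
        assert height == 3.0

    def test_missing_tips_listed(self):
        tree = load_tree("((A:1,B:1):2,C:3);")
        with pytest.raises(KeyError, match="Zeta"):
            tree_matrices(tree, ["A", "Zeta"])

    def test_name_normalization(self):
        # unquoted underscores read as spaces per the Newick convention;
        # lookup succeeds either way after normalization
        tree = load_tree("((Poa_alpina:1,B:1):2,C:3);")
        vcv, _, _ = tree_matrices(tree, ["Poa alpina", "B", "C"])
        assert vcv[0, 1] == 2.0


class TestPhyloLogistic:
    def test_star_tree_equals_firth_oracle(self, star_tree):
        tree, labels = star_tree
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, len(labels))
        y = (rng.random(len(labels)) < expit(-0.3 + 1.2 * x)).astype(float)
        m = PhyloLogisticRegression().fit(
            pd.DataFrame({"x": x}, index=labels), y, tree=tree
        )
        oracle = firth_logistic_oracle(x.reshape(-1, 1), y)
        got = np.concatenate([[m.intercept_], m.coef_])
        assert np.max(np.abs(got - oracle)) < 1e-4
        assert np.isinf(m.alpha_)

    def test_alpha_infinity_equals_firth_on_real_tree(self):
        tree = simulate_phylogeny(80, seed=5)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 80)
        y = simulate_binary_trait(
            tree, pd.DataFrame({"x": x}, index=labels), (0.2, 0.8), 3.0, seed=5
        ).to_numpy(float)
        m = PhyloLogisticRegression(alpha=np.inf).fit(
            pd.DataFrame({"x": x}, index=labels), y, tree=tree
        )
        oracle = firth_logistic_oracle(x.reshape(-1, 1), y)
        got = np.concatenate([[m.intercept_], m.coef_])
        assert np.max(np.abs(got - oracle)) < 1e-4

    def test_constant_predictor_rejected(self, star_tree):
        tree, labels = star_tree
        X = pd.DataFrame({"x": np.ones(len(labels))}, index=labels)
        y = np.tile([0.0, 1.0], len(labels) // 2)
        with pytest.raises(ValueError, match="constant"):
            PhyloLogisticRegression().fit(X, y, tree=tree)

    def test_tip_mismatch_reported(self, star_tree):
        tree, labels = star_tree
        X = pd.DataFrame({"x": [0.1, 0.2]}, index=["ghost1", "ghost2"])
        with pytest.raises(KeyError, match="ghost"):
            PhyloLogisticRegression().fit(X, np.array([0.0, 1.0]), tree=tree)

    def test_tip_permutation_invariance(self):
        tree = simulate_phylogeny(50, seed=9)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        X = pd.DataFrame({"x": x}, index=labels)
        y = simulate_binary_trait(tree, X, (0.0, 1.0), 3.0, seed=9)
        m1 = PhyloLogisticRegression().fit(X, y.to_numpy(float), tree=tree)
        perm = rng.permutation(50)
        Xp = X.iloc[perm]
        yp = y.iloc[perm]
        m2 = PhyloLogisticRegression().fit(Xp, yp.to_numpy(float), tree=tree)
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-6)
        np.testing.assert_allclose(m1.intercept_, m2.intercept_, atol=1e-6)

    def test_slope_recovery_on_simulated_trees(self):
        """Mean slope estimate across replicates stays near the generating value."""
        est = []
        for rep in range(40):
            tree = simulate_phylogeny(100, seed=rep)
            labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
            rng = np.random.default_rng(200 + rep)
            X = pd.DataFrame({"x": rng.normal(0, 1, 100)}, index=labels)
            y = simulate_binary_trait(tree, X, (0.0, 1.0), 3.0, seed=rep)
            m = PhyloLogisticRegression().fit(X, y.to_numpy(float), tree=tree)
            if m.converged_:
                est.append(m.coef_[0])
        assert abs(np.mean(est) - 1.0) < 0.2

    def test_bootstrap_deterministic_under_seed(self, star_tree):
        tree, labels = star_tree
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, len(labels))
        y = (rng.random(len(labels)) < expit(0.8 * x)).astype(float)
        X = pd.DataFrame({"x": x}, index=labels)
        m = PhyloLogisticRegression().fit(X, y, tree=tree)
        ci1 = np.array(m.bootstrap_ci(n_boot=50, seed=77))
        ci2 = np.array(m.bootstrap_ci(n_boot=50, seed=77))
        np.testing.assert_array_equal(ci1, ci2)

    def test_bootstrap_stable_in_replicate_count(self, star_tree):
        tree, labels = star_tree
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, len(labels))
        y = (rng.random(len(labels)) < expit(0.8 * x)).astype(float)
        X = pd.DataFrame({"x": x}, index=labels)
        m = PhyloLogisticRegression().fit(X, y, tree=tree)
        ci_small = np.array(m.bootstrap_ci(n_boot=150, seed=1))
        ci_big = np.array(m.bootstrap_ci(n_boot=900, seed=2))
        width = ci_big[1, 1] - ci_big[1, 0]
        assert np.max(np.abs(ci_small - ci_big)) < 0.5 * width


class TestPGLS:
    def test_star_tree_equals_ols(self, star_tree):
        tree, labels = star_tree
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, len(labels))
        y = 1.5 + 0.7 * x + rng.normal(0, 0.3, len(labels))
        fit = pgls_fit(tree, x, y, labels)
        slope, intercept = np.polyfit(x, y, 1)
        assert abs(fit.slope - slope) < 1e-10
        assert abs(fit.intercept - intercept) < 1e-10

    def test_exact_linear_relation(self, star_tree):
        tree, labels = star_tree
        x = np.linspace(-1, 1, len(labels))
        fit = pgls_fit(tree, x, 2 * x, labels)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_matrix_algebra_gls_oracle(self):
        tree = simulate_phylogeny(40, seed=3)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        C, _, _ = tree_matrices(tree, labels)
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(40))
        x = L @ rng.normal(0, 1, 40)
        y = 0.5 * x + L @ rng.normal(0, 0.5, 40)
        fit = pgls_fit(tree, x, y, labels)
        Xd = np.column_stack([np.ones(40), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(Xd.T @ Ci @ Xd, Xd.T @ Ci @ y)
        assert abs(fit.intercept - beta[0]) < 1e-8
        assert abs(fit.slope - beta[1]) < 1e-8

    def test_r2_in_unit_interval(self, star_tree):
        tree, labels = star_tree
        rng = np.random.default_rng(8)
        fit = pgls_fit(tree, rng.normal(0, 1, 60), rng.normal(0, 1, 60), labels)
        assert 0.0 <= fit.r2 <= 1.0

    def test_singular_design_rejected(self, star_tree):
        tree, labels = star_tree
        x = np.ones(len(labels))
        with pytest.raises(np.linalg.LinAlgError):
            PGLS().fit(x.reshape(-1, 1), x, tree=tree, species=labels)


class TestLeafTraitPCA:
    def test_orthogonal_unit_traits_share_variance(self):
        base = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        df = pd.DataFrame(base, columns=["sla", "leaf_n", "cn_ratio"])
        est = LeafTraitPCA().fit(df)
        np.testing.assert_allclose(est.explained_variance_ratio_, [1 / 3] * 3, atol=1e-12)

    def test_collinear_n_and_cn_share_dim1_with_sign_convention(self, rng):
        leaf_n = rng.normal(20, 3, 50)
        cn = 60 - 2 * leaf_n  # perfectly collinear, opposite sign
        sla = rng.normal(15, 2, 50)
        scores, loadings, _ = leaf_trait_pca(sla, leaf_n, cn)
        # dim1: leaf N positive, C:N negative; dim2: SLA positive
        assert loadings[0, 1] > 0 and loadings[0, 2] < 0
        assert loadings[1, 0] > 0
        corr = np.corrcoef(scores[:, 0], leaf_n)[0, 1]
        assert corr > 0.99

    def test_variance_fractions_sum_to_one_and_scores_centered(self, rng):
        df = pd.DataFrame(
            rng.lognormal(2, 0.3, (30, 3)), columns=["sla", "leaf_n", "cn_ratio"]
        )
        est = LeafTraitPCA().fit(df)
        assert est.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-12)
        scores = est.transform(df)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"sla": [1.0, 1, 1], "leaf_n": [1.0, 2, 3], "cn_ratio": [3.0, 2, 1]})
        with pytest.raises(ValueError, match="sla"):
            LeafTraitPCA().fit(df)
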