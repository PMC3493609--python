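"""NIPALS PLS-DA/OPLS-DA, Q², AUROC and external validation."""

import numpy as np
import pytest

from lipidcohort.core import ValidationError
from lipidcohort.multivariate import (
    auroc,
    external_validation,
    fit_opls_da,
    fit_pls_da,
    fit_preprocessor,
    partition_test_blocks,
    q_squared,
)


def _instance(seed, n=24, p=6, effect=2.0):
    rng = np.random.default_rng(seed)
    n0 = n // 2
    Xl = rng.normal(0, 1, (n, p))
    Xl[n0:, : p // 2] += effect
    y = np.r_[np.zeros(n0), np.ones(n - n0)]
    return np.exp(Xl), y


class TestPreprocessor:
    def test_training_columns_standardized(self):
        X, _ = _instance(0)
        pre = fit_preprocessor(X)
        Z = pre.transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_constant_feature_rejected_by_name(self):
        X = np.abs(np.random.default_rng(0).normal(2, 1, (10, 2))) + 0.1
        X[:, 1] = 3.0
        with pytest.raises(ValidationError, match="foo"):
            fit_preprocessor(X, feature_names=["ok", "foo"])

    def test_roundtrip_inverse(self):
        X, _ = _instance(1)
        pre = fit_preprocessor(X)
        assert np.allclose(pre.inverse_transform(pre.transform(X)), X, rtol=1e-10)


class TestPLSDA:
    def test_first_weight_proportional_to_xty(self):
        X, y = _instance(2)
        pre = fit_preprocessor(X)
        Z = pre.transform(X)
        model = fit_pls_da(Z, y, n_components=1)
        w_oracle = Z.T @ (y - y.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        assert np.allclose(model.weights[:, 0], w_oracle, atol=1e-12)

    def test_single_feature_equals_univariate_ols(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 20)
        Z = ((z - z.mean()) / z.std(ddof=1))[:, None]
        y = (z > 0).astype(float)
        model = fit_pls_da(Z, y, n_components=1)
        yc = y - y.mean()
        beta = float(Z[:, 0] @ yc / (Z[:, 0] @ Z[:, 0]))
        assert np.allclose(model.predict(Z), Z[:, 0] * beta + y.mean(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_vectors_mutually_orthogonal(self, seed):
        X, y = _instance(seed, n=30, p=8)
        Z = fit_preprocessor(X).transform(X)
        model = fit_pls_da(Z, y, n_components=4)
        T = model.scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_separable_groups_reach_perfect_training_auroc(self):
        X, y = _instance(4, effect=6.0)
        Z = fit_preprocessor(X).transform(X)
        assert fit_pls_da(Z, y, 2).auroc_train == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_predictions_match_independent_pls_implementation(self, seed):
        """Fitted values agree with scikit-learn's PLSRegression (an
        independent NIPALS implementation) to machine precision."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _instance(seed + 30, n=30, p=8, effect=1.5)
        Z = fit_preprocessor(X).transform(X)
        mine = fit_pls_da(Z, y, n_components=3).predict(Z)
        ref = PLSRegression(n_components=3, scale=False).fit(Z, y)
        assert np.abs(mine - ref.predict(Z).ravel()).max() < 1e-10

    def test_excess_components_rejected(self):
        X, y = _instance(5, n=10, p=3)
        Z = fit_preprocessor(X).transform(X)
        with pytest.raises(ValidationError):
            fit_pls_da(Z, y, n_components=4)


class TestOPLSDA:
    def test_zero_orthogonal_equals_one_component_pls(self):
        X, y = _instance(6)
        Z = fit_preprocessor(X).transform(X)
        opls = fit_opls_da(Z, y, n_orthogonal=0)
        pls = fit_pls_da(Z, y, n_components=1)
        assert np.allclose(opls.predict(Z), pls.predict(Z), atol=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_predictive_equivalence_with_pls(self, k):
        """OPLS-DA with k orthogonal components reproduces the fitted
        values of (k+1)-component PLS-DA."""
        X, y = _instance(7, n=30, p=10)
        Z = fit_preprocessor(X).transform(X)
        opls = fit_opls_da(Z, y, n_orthogonal=k)
        pls = fit_pls_da(Z, y, n_components=k + 1)
        assert np.abs(opls.predict(Z) - pls.predict(Z)).max() < 1e-8

    def test_orthogonal_scores_uncorrelated_with_labels(self):
        X, y = _instance(8, n=40, p=12)
        Z = fit_preprocessor(X).transform(X)
        model = fit_opls_da(Z, y, n_orthogonal=3)
        yc = y - y.mean()
        for k in range(3):
            assert abs(model.ortho_scores[:, k] @ yc) < 1e-10

    def test_excess_orthogonal_rejected(self):
        X, y = _instance(9, n=8, p=3)
        Z = fit_preprocessor(X).transform(X)
        with pytest.raises(ValidationError):
            fit_opls_da(Z, y, n_orthogonal=5)


class TestQSquared:
    def test_perfect_prediction_gives_one(self):
        # y is a deterministic linear readout of the single feature
        rng = np.random.default_rng(10)
        n = 28
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        Xl = (y * 4 - 2 + rng.normal(0, 1e-9, n))[:, None]
        q2 = q_squared(np.exp(Xl), y, n_components=1, n_folds=7, seed=0)
        assert q2 == pytest.approx(1.0, abs=1e-4)

    def test_loo_matches_handrolled_press(self):
        """Leave-one-out on 6 subjects against a direct PRESS oracle."""
        rng = np.random.default_rng(11)
        Xl = rng.normal(0, 1, (6, 3))
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.exp(Xl)
        press = tss = 0.0
        for i in range(6):
            tr = [j for j in range(6) if j != i]
            mu, sd = Xl[tr].mean(0), Xl[tr].std(0, ddof=1)
            Zt, Ze = (Xl[tr] - mu) / sd, (Xl[[i]] - mu) / sd
            ym = y[tr].mean()
            model = fit_pls_da(Zt, y[tr], n_components=1)
            pred = model.predict(Ze) - ym
            press += float((y[i] - ym - pred[0]) ** 2)
            tss += float((y[i] - ym) ** 2)
        oracle = 1.0 - press / tss
        # leave-one-out = 6 folds; stratified assignment with 3+3 classes
        # puts one subject per fold for any seed
        q2 = q_squared(X, y, n_components=1, n_folds=6, seed=0)
        assert q2 == pytest.approx(oracle, abs=1e-12)

    def test_single_class_fold_rejected(self):
        X, y = _instance(12, n=10)
        with pytest.raises(ValidationError):
            q_squared(X, np.zeros(10), n_folds=5)

    def test_q2_not_above_r2(self):
        X, y = _instance(13, n=30, p=8, effect=1.0)
        Z = fit_preprocessor(X).transform(X)
        r2 = fit_pls_da(Z, y, 2).r2y
        q2 = q_squared(X, y, n_components=2, n_folds=7, seed=0)
        assert q2 <= r2 + 1e-9


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        s = rng.integers(0, 10, n).astype(float)  # ties likely
        y = rng.integers(0, 2, n).astype(float)
        if len(np.unique(y)) < 2:
            y[0], y[-1] = 0, 1
        pos, neg = s[y == 1], s[y == 0]
        oracle = (
            (pos[:, None] > neg[None, :]).sum()
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        ) / (len(pos) * len(neg))
        assert auroc(s, y) == pytest.approx(oracle)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(20)
        s = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30).astype(float)
        y[:2] = [0, 1]
        assert auroc(np.exp(3 * s), y) == pytest.approx(auroc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([1, 2], [1, 1])


class TestExternalValidation:
    def test_test_blocks_partition_cohort(self):
        """Study-sized cohort (12+43): test sets of 18, 18, 19 subjects
        covering everyone exactly once."""
        y = np.r_[np.zeros(12), np.ones(43)]
        blocks = partition_test_blocks(y, 3, np.random.default_rng(0))
        sizes = sorted(len(b) for b in blocks)
        assert sizes == [18, 18, 19]
        assert sorted(np.concatenate(blocks).tolist()) == list(range(55))

    def test_same_seed_same_splits(self):
        X, y = _instance(14, n=30, p=6)
        r1 = external_validation(X, y, seed=5)
        r2 = external_validation(X, y, seed=5)
        for a, b in zip(r1.test_sets, r2.test_sets):
            assert (a == b).all()
        assert r1.test_q2 == r2.test_q2

    def test_strong_effect_gives_high_test_auroc(self, paper_cohort):
        feats = paper_cohort.modeling_metabolites()
        X = paper_cohort.concentrations[feats].to_numpy()
        y = paper_cohort.labels01()
        report = external_validation(X, y, seed=0)
        assert report.mean_test_auroc > 0.9
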