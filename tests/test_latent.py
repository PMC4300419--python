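import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from biosol.latent import (ModelError, NipalsPLS, PCAModel, choose_components,
                           dmodx, hotelling_t2, q2_crossval, vip)
from biosol.synthetic import SyntheticSpec, generate_latent_dataset
from conftest import random_regression


class TestNipalsPLS:
    def test_single_proportional_descriptor_fits_exactly(self):
        x = pd.DataFrame({"d": np.arange(10, dtype=float)})
        y = 3.0 * x["d"] - 1.0
        m = NipalsPLS(n_components=1).fit(x, y)
        assert m.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_univariate_matches_least_squares(self, rng):
        x = pd.DataFrame({"d": rng.standard_normal(30)})
        y = pd.Series(2.0 * x["d"].to_numpy() + rng.standard_normal(30) * 0.3)
        m = NipalsPLS(n_components=1).fit(x, y)
        slope, intercept = np.polyfit(x["d"], y, 1)
        assert np.allclose(m.predict(x), slope * x["d"] + intercept, atol=1e-10)

    def test_two_latent_structure_needs_two_components(self):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=60, p=20, k=2, n_informative=8, noise_sd=0.2, seed=11))
        r2 = [NipalsPLS(n_components=a).fit(X, y).r2_ for a in (1, 2)]
        assert r2[1] > r2[0]

    def test_training_predictions_reproduce_fitted(self, rng):
        X, y = random_regression(rng)
        m = NipalsPLS(n_components=3).fit(X, y)
        assert np.allclose(m.predict(X), m.fitted_, atol=1e-10)

    def test_centered_observation_predicts_mean(self, rng):
        X, y = random_regression(rng)
        m = NipalsPLS(n_components=2).fit(X, y)
        at_mean = pd.DataFrame([X.mean()], columns=X.columns)
        assert m.predict(at_mean)[0] == pytest.approx(m.y_mean_, abs=1e-10)

    def test_matches_sklearn_predictions(self, rng):
        for _ in range(5):
            X, y = random_regression(rng, n=30, p=6)
            m = NipalsPLS(n_components=3).fit(X, y)
            sk = PLSRegression(n_components=3, scale=False).fit(X.to_numpy(),
                                                                y.to_numpy())
            assert np.allclose(m.predict(X), sk.predict(X.to_numpy()).ravel(),
                               atol=1e-10)

    def test_score_orthogonality(self, rng):
        X, y = random_regression(rng, n=50, p=10)
        T = NipalsPLS(n_components=4).fit(X, y).x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_row_permutation_permutes_predictions(self, rng):
        X, y = random_regression(rng)
        perm = rng.permutation(len(y))
        m1 = NipalsPLS(n_components=2).fit(X, y)
        m2 = NipalsPLS(n_components=2).fit(X.iloc[perm], y.iloc[perm])
        assert np.allclose(m1.predict(X)[perm], m2.predict(X.iloc[perm]), atol=1e-10)

    def test_degenerate_inputs(self, rng):
        X, y = random_regression(rng)
        with pytest.raises(ModelError):
            NipalsPLS(n_components=100).fit(X, y)
        with pytest.raises(ModelError):
            NipalsPLS(n_components=1).fit(X, np.ones(len(y)))

    def test_column_mismatch_is_schema_error(self, rng):
        X, y = random_regression(rng)
        m = NipalsPLS(n_components=2).fit(X, y)
        bad = X.copy()
        bad.columns = [c + "_renamed" for c in X.columns]
        with pytest.raises(ModelError):
            m.predict(bad)


class TestPCA:
    def test_rank_one_fully_explained(self, rng):
        u = rng.standard_normal(15)
        v = rng.standard_normal(4)
        X = pd.DataFrame(np.outer(u - u.mean(), v))
        m = PCAModel(n_components=1).fit(X)
        assert m.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        m = PCAModel(n_components=5).fit(X)
        cov = np.cov(X.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        assert np.allclose(m.explained_variance_, evals[order], atol=1e-8)
        for a in range(5):
            dot = abs(evecs[:, order[a]] @ m.loadings_[:, a])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        L = PCAModel(n_components=4).fit(X).loadings_
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_row_permutation_permutes_scores_only(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 4)))
        perm = rng.permutation(25)
        m1 = PCAModel(n_components=3).fit(X)
        m2 = PCAModel(n_components=3).fit(X.iloc[perm])
        assert np.allclose(m1.loadings_, m2.loadings_, atol=1e-10)
        assert np.allclose(m1.scores_[perm], m2.scores_, atol=1e-10)


class TestHotelling:
    def test_zero_at_score_space_origin(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        m = PCAModel(n_components=2).fit(X)
        t2, _ = hotelling_t2(m, pd.DataFrame([X.mean()], columns=X.columns))
        assert t2[0] == pytest.approx(0.0, abs=1e-20)

    def test_training_exceedance_near_alpha(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((2000, 6)))
        m = PCAModel(n_components=3).fit(X)
        t2, lim = hotelling_t2(m)
        assert (t2 > lim).mean() == pytest.approx(0.05, abs=0.015)

    def test_sign_flip_invariance(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        m = PCAModel(n_components=2).fit(X)
        t2_a, _ = hotelling_t2(m)
        m.loadings_[:, 0] *= -1
        m.scores_[:, 0] *= -1
        t2_b, _ = hotelling_t2(m)
        assert np.allclose(t2_a, t2_b)


class TestDModX:
    def test_zero_for_observation_in_model_plane(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)))
        m = PCAModel(n_components=2).fit(X)
        in_plane = m.x_mean_ + m.scores_[3] @ m.loadings_.T
        d, _ = dmodx(m, pd.DataFrame([in_plane], columns=X.columns))
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_training_mean_near_one(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((200, 30)))
        m = PCAModel(n_components=2).fit(X)
        d, _ = dmodx(m)
        assert d.mean() == pytest.approx(1.0, abs=0.1)

    def test_distance_linear_in_orthogonal_residual(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)))
        m = PCAModel(n_components=2).fit(X)
        base = m.x_mean_ + m.scores_[0] @ m.loadings_.T
        resid = np.zeros(6)
        resid[:] = rng.standard_normal(6)
        resid -= m.loadings_ @ (m.loadings_.T @ resid)  # orthogonal part
        obs = pd.DataFrame([base + resid, base + 2 * resid], columns=X.columns)
        d, _ = dmodx(m, obs)
        assert d[1] == pytest.approx(2 * d[0], rel=1e-9)


class TestCrossValidation:
    def test_exact_linear_relation(self, rng):
        X, y = random_regression(rng, noise=0.0)
        cv = q2_crossval(X, y, n_components=X.shape[1])
        assert cv.q2[-1] > 0.999

    def test_pure_noise_gives_nonpositive_q2(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((200, 10)))
        y = pd.Series(rng.standard_normal(200))
        cv = q2_crossval(X, y, n_components=2)
        assert cv.q2[-1] <= 0.0

    def test_fold_sizes_balanced(self, rng):
        X, y = random_regression(rng, n=45)
        cv = q2_crossval(X, y, n_components=1, groups=7)
        sizes = np.bincount(cv.fold_assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_matches_brute_force_oracle(self, rng):
        """Implementation vs an independent per-fold loop over sklearn's PLS."""
        X, y = random_regression(rng, n=35, p=6)
        a = 3
        cv = q2_crossval(X, y, n_components=a, groups=7)
        folds = np.arange(len(y)) % 7
        press = np.zeros(a)
        for g in range(7):
            tr, te = folds != g, folds == g
            for comp in range(1, a + 1):
                sk = PLSRegression(n_components=comp, scale=False).fit(
                    X.to_numpy()[tr], y.to_numpy()[tr])
                pred = sk.predict(X.to_numpy()[te]).ravel()
                press[comp - 1] += np.sum((y.to_numpy()[te] - pred) ** 2)
        ss = np.sum((y - y.mean()) ** 2)
        assert np.allclose(cv.q2, 1 - press / ss, atol=1e-10)

    def test_too_many_groups(self, rng):
        X, y = random_regression(rng, n=5, p=3)
        with pytest.raises(ModelError):
            q2_crossval(X, y, n_components=1, groups=10)


class TestChooseComponents:
    def test_single_latent_data_chooses_one(self):
        X, y, _ = generate_latent_dataset(
            SyntheticSpec(n=60, p=30, k=1, n_informative=6, noise_sd=0.1, seed=2))
        a, _ = choose_components(X, y, max_a=5)
        assert a == 1

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((80, 10)))
        y = pd.Series(rng.standard_normal(80))
        a, cv = choose_components(X, y, max_a=4)
        assert a == 1 and cv.q2_at_chosen <= 0

    def test_infinite_threshold_forces_one(self, rng):
        X, y = random_regression(rng)
        a, _ = choose_components(X, y, max_a=5, threshold=np.inf)
        assert a == 1


class TestVIP:
    def test_single_descriptor_is_unity(self, rng):
        x = pd.DataFrame({"d": rng.standard_normal(20)})
        y = pd.Series(x["d"] * 2 + rng.standard_normal(20) * 0.1)
        m = NipalsPLS(n_components=1).fit(x, y)
        assert vip(m)["d"] == pytest.approx(1.0, abs=1e-12)

    def test_normalization_identity(self, rng):
        for _ in range(5):
            X, y = random_regression(rng, n=40, p=12)
            m = NipalsPLS(n_components=3).fit(X, y)
            v = vip(m)
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_informative_descriptors_outrank_noise(self):
        X, y, truth = generate_latent_dataset(
            SyntheticSpec(n=80, p=60, k=2, n_informative=5, noise_sd=0.3, seed=4))
        m = NipalsPLS(n_components=2).fit(X, y)
        v = vip(m)
        assert v[truth.informative].median() > v.drop(truth.informative).median()
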