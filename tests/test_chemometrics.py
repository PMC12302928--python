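import numpy as np
import pandas as pd
import pytest

from flavoromics.chemometrics import (
    cross_validated_q2,
    fit_oplsda,
    fit_pca,
    log_intensities,
    vip_scores,
)


def random_X(rng, n=9, p=30):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{i}" for i in range(p)],
    )


def pls1_oracle(X, y, scale=True):
    """Independent one-component PLS1: closed form, no deflation needed."""
    Xn = np.asarray(X, dtype=float)
    center = Xn.mean(axis=0)
    sd = Xn.std(axis=0, ddof=1) if scale else np.ones(Xn.shape[1])
    Xc = (Xn - center) / sd
    yc = y - y.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    t = Xc @ w
    q = float(yc @ t / (t @ t))
    r2y = 1.0 - float(np.sum((yc - t * q) ** 2) / np.sum(yc**2))
    return w, t, q, r2y


class TestPca:
    def test_identical_samples_get_identical_scores(self, rng):
        X = random_X(rng, 6, 10)
        X.iloc[1] = X.iloc[0]
        model = fit_pca(X, k=2)
        np.testing.assert_allclose(
            model.scores.iloc[0], model.scores.iloc[1], atol=1e-10
        )

    def test_rank_one_matrix_explained_fully_by_pc1(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=8)
        X = pd.DataFrame(np.outer(u, v))
        X.columns = [f"f{i}" for i in range(8)]
        model = fit_pca(X, k=2, scale=False)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle_up_to_sign(self, rng):
        X = random_X(rng)
        model = fit_pca(X, k=4)
        Xs = (X - X.mean()) / X.std(ddof=1)
        cov = Xs.T @ Xs / 1.0
        evals, evecs = np.linalg.eigh(cov.to_numpy())
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for a in range(4):
            got = model.loadings.iloc[:, a].to_numpy()
            want = evecs[:, a]
            assert min(
                np.abs(got - want).max(), np.abs(got + want).max()
            ) < 1e-8
        np.testing.assert_allclose(
            model.explained_variance_fraction,
            (evals / evals.sum())[:4],
            atol=1e-10,
        )

    def test_loadings_orthonormal_and_fractions_non_increasing(self, rng):
        model = fit_pca(random_X(rng), k=5)
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-10)
        frac = model.explained_variance_fraction
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1 + 1e-12

    def test_reconstruction_with_all_components(self, rng):
        X = random_X(rng, 7, 5)
        model = fit_pca(X, k=5)
        recon = (
            model.scores.to_numpy() @ model.loadings.to_numpy().T * model.scale
            + model.center
        )
        # 7 samples, 5 features: all 5 components reproduce the input
        np.testing.assert_allclose(recon, X.to_numpy(), atol=1e-10)

    def test_constant_feature_error_names_feature(self, rng):
        X = random_X(rng, 6, 4)
        X["f2"] = 3.14
        with pytest.raises(ValueError, match="f2"):
            fit_pca(X, k=2)

    def test_sign_convention_deterministic(self, rng):
        X = random_X(rng)
        m1, m2 = fit_pca(X, k=3), fit_pca(X.copy(), k=3)
        pd.testing.assert_frame_equal(m1.loadings, m2.loadings)
        for a in range(3):
            col = m1.loadings.iloc[:, a].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0


class TestOplsda:
    labels6 = ["A"] * 3 + ["B"] * 3

    def test_perfect_predictor_has_largest_weight_and_vip(self, rng):
        X = random_X(rng, 10, 8)
        y = np.array([1.0] * 5 + [0.0] * 5)
        X["f0"] = y * 2 + 3
        model = fit_oplsda(X, ["A"] * 5 + ["B"] * 5, n_ortho=0)
        assert model.vip.idxmax() == "f0"
        assert np.argmax(np.abs(model.w)) == list(X.columns).index("f0")

    @pytest.mark.parametrize("seed", range(5))
    def test_n_ortho_zero_equals_pls1_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = random_X(rng)
        labels = ["A"] * 4 + ["B"] * 5
        y = np.array([1.0] * 4 + [0.0] * 5)
        model = fit_oplsda(X, labels, n_ortho=0)
        w, t, q, r2y = pls1_oracle(X, y)
        sign = np.sign(w[np.argmax(np.abs(w))])
        np.testing.assert_allclose(model.w, w * sign, atol=1e-10)
        np.testing.assert_allclose(model.t, t * sign, atol=1e-10)
        assert model.q == pytest.approx(q * sign, abs=1e-10)
        assert model.r2y == pytest.approx(r2y, abs=1e-10)

    def test_matches_sklearn_pls_weight_direction(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = random_X(rng)
        y = np.array([1.0] * 4 + [0.0] * 5)
        model = fit_oplsda(X, ["A"] * 4 + ["B"] * 5, n_ortho=0)
        pls = sklearn.PLSRegression(n_components=1, scale=True).fit(X, y)
        w_sk = pls.x_weights_[:, 0]
        np.testing.assert_allclose(
            np.abs(model.w), np.abs(w_sk), atol=1e-8
        )

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X = random_X(rng, 12, 20)
        labels = ["A"] * 6 + ["B"] * 6
        y = np.array([1.0] * 6 + [0.0] * 6)
        model = fit_oplsda(X, labels, n_ortho=2)
        yc = y - y.mean()
        for a in range(2):
            assert abs(model.t_ortho[:, a] @ yc) < 1e-8
            assert abs(model.t_ortho[:, a] @ model.t) < 1e-8

    def test_predictive_score_invariant_to_captured_orthogonal_structure(self, rng):
        # rank-one y-orthogonal structure is removed exactly by one
        # orthogonal component, restoring the clean predictive score
        n, p = 10, 15
        y = np.array([1.0] * 5 + [0.0] * 5)
        yc = y - y.mean()
        a = rng.normal(size=p)
        X0 = pd.DataFrame(np.outer(yc, a), columns=[f"f{i}" for i in range(p)])
        z = rng.normal(size=n)
        z = z - z.mean()
        z -= (z @ yc) / (yc @ yc) * yc  # exactly y-orthogonal
        b = rng.normal(size=p)
        X1 = X0 + np.outer(z, 5 * b)
        labels = ["A"] * 5 + ["B"] * 5
        t0 = fit_oplsda(X0, labels, n_ortho=0, scale=False).t
        t1 = fit_oplsda(X1, labels, n_ortho=1, scale=False).t
        assert np.abs(t1 - t0).max() < 1e-6

    def test_single_class_and_excess_ortho_errors(self, rng):
        X = random_X(rng, 6, 5)
        with pytest.raises(ValueError, match="two classes"):
            fit_oplsda(X, ["A"] * 6, n_ortho=0)
        with pytest.raises(ValueError, match="n_ortho"):
            fit_oplsda(X, self.labels6, n_ortho=5)

    def test_r2y_in_unit_interval_and_q2_below_r2y(self, small_study):
        from flavoromics.preprocess import preprocess_table

        mets, _ = preprocess_table(small_study.metabolites)
        sub = mets.subset_groups(("GL", "XZ"))
        model = fit_oplsda(
            log_intensities(sub), list(sub.group_labels), n_ortho=1, cv="loo"
        )
        assert 0.0 <= model.r2y <= 1.0
        assert model.q2 <= model.r2y + 1e-9


class TestVip:
    def test_single_feature_vip_is_one(self):
        X = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 4.0]})
        model = fit_oplsda(X, ["A", "A", "B", "B"], n_ortho=0)
        assert model.vip["f0"] == pytest.approx(1.0, abs=1e-12)

    def test_two_features_one_zero_weight(self):
        # f0 encodes the classes, f1 is constant-per-class mirror of f0 scaled
        y = np.array([1.0, 1.0, 0.0, 0.0])
        X = pd.DataFrame({"f0": y * 2 + 1, "f1": [5.0, 3.0, 5.0, 3.0]})
        model = fit_oplsda(X, ["A", "A", "B", "B"], n_ortho=0, scale=False)
        np.testing.assert_allclose(
            sorted(model.vip, reverse=True), [np.sqrt(2), 0.0], atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_formula_by_hand_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = random_X(rng, 9, 20)
        labels = ["A"] * 4 + ["B"] * 5
        y = np.array([1.0] * 4 + [0.0] * 5)
        model = fit_oplsda(X, labels, n_ortho=0)
        # hand formula over the single predictive component
        w, t, q, _ = pls1_oracle(X, y)
        yc = y - y.mean()
        ssy = (yc @ t) ** 2 / (t @ t)
        vip_hand = np.sqrt(20 * (w / np.linalg.norm(w)) ** 2 * ssy / ssy)
        np.testing.assert_allclose(model.vip.to_numpy(), vip_hand, atol=1e-10)
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_total_vip_variant_returns_all_features(self, rng):
        X = random_X(rng, 10, 12)
        model = fit_oplsda(X, ["A"] * 5 + ["B"] * 5, n_ortho=1)
        total = vip_scores(model, include_orthogonal=True)
        assert len(total) == 12
        assert (total >= 0).all()


class TestQ2:
    def test_perfect_noiseless_predictor_loo(self):
        y = np.array([1.0] * 4 + [0.0] * 4)
        X = pd.DataFrame({"f0": y}, dtype=float)
        q2 = cross_validated_q2(X, ["A"] * 4 + ["B"] * 4, n_ortho=0, folds="loo")
        assert q2 > 0.99

    def test_permuted_labels_give_low_q2(self):
        rng = np.random.default_rng(21)
        X = random_X(rng, 12, 30)
        hits = 0
        for _ in range(50):
            labels = list(rng.permutation(["A"] * 6 + ["B"] * 6))
            q2 = cross_validated_q2(X, labels, n_ortho=0, folds="loo")
            hits += q2 < 0.4
        assert hits >= 45  # >= 90% of permutations

    def test_loo_matches_manual_per_sample_refit_oracle(self):
        rng = np.random.default_rng(5)
        X = random_X(rng, 6, 5)
        labels = ["A"] * 3 + ["B"] * 3
        y = np.array([1.0] * 3 + [0.0] * 3)
        got = cross_validated_q2(X, labels, n_ortho=0, folds="loo")
        press = 0.0
        for i in range(6):
            train = [j for j in range(6) if j != i]
            Xtr, ytr = X.iloc[train], y[train]
            w, t, q, _ = pls1_oracle(Xtr, ytr)
            center = Xtr.to_numpy().mean(axis=0)
            sd = Xtr.to_numpy().std(axis=0, ddof=1)
            x_new = (X.iloc[i].to_numpy() - center) / sd
            pred = (x_new @ w) * q + ytr.mean()
            press += (y[i] - pred) ** 2
        oracle = 1 - press / np.sum((y - y.mean()) ** 2)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_fold_count_out_of_range_is_an_error(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 3)))
        X.columns = ["a", "b", "c"]
        with pytest.raises(ValueError, match="folds"):
            cross_validated_q2(X, ["A", "A", "B", "B"], n_ortho=0, folds=1)


class TestLogTransform:
    def test_rejects_missing_and_nonpositive(self, tiny_table):
        import dataclasses

        bad = tiny_table.values.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            log_intensities(dataclasses.replace(tiny_table, values=bad))
        zero = tiny_table.values.copy()
        zero.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            log_intensities(dataclasses.replace(tiny_table, values=zero))
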