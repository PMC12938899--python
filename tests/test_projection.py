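"""PCA/PLS-DA decompositions, VIP, and CV component choice."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from evpanel.exceptions import ConfigurationError, ContractError, DataIntegrityError
from evpanel.projection import (
    PLSDiscriminant,
    choose_components_cv,
    fit_pca,
    fit_plsda,
    vip,
)


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        x = np.column_stack([col, col])  # duplicated single feature
        model = fit_pca(x, n_components=1)
        assert model.variance_explained[0] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 5))
        model = fit_pca(x, n_components=5)
        assert np.allclose(model.variance_explained, 0.2, atol=0.03)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 6))
        model = fit_pca(x, n_components=6)
        xc = (x - model.scaling_mean.to_numpy()) / model.scaling_sd.to_numpy()
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, xc, atol=1e-8)

    def test_scores_centered_and_ordered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 8)) @ np.diag([5, 3, 1, 1, 1, 1, 1, 1])
        model = fit_pca(x, n_components=4, scale=False)
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-8
        assert (np.diff(model.variance_explained) <= 1e-12).all()

    def test_nan_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(DataIntegrityError):
            fit_pca(x, 2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 5))
        m1, m2 = fit_pca(x, 3), fit_pca(x.copy(), 3)
        assert np.allclose(m1.loadings, m2.loadings)
        for c in m1.loadings.columns:
            col = m1.loadings[c]
            assert col.iloc[np.abs(col.to_numpy()).argmax()] > 0


class TestPlsda:
    def _planted(self, n=40, p=10, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, p))
        x[:, 0] += 3 * y
        return x, y

    def test_separating_feature_dominates_lv1(self):
        x, y = self._planted()
        est = PLSDiscriminant(n_components=2).fit(x, y)
        assert np.abs(est.x_weights_[:, 0]).argmax() == 0

    def test_matches_sklearn_pls_scores(self):
        """Independent route: sklearn's NIPALS PLS2 on the same centered
        indicator matrix produces the same latent scores up to sign."""
        x, y = self._planted(seed=5)
        est = PLSDiscriminant(n_components=3, scale=True).fit(x, y)
        Y = np.column_stack([(y == 0), (y == 1)]).astype(float)
        sk = PLSRegression(n_components=3, scale=True).fit(x, Y)
        for a in range(3):
            c = np.corrcoef(est.x_scores_[:, a], sk.x_scores_[:, a])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-6)

    def test_transform_truncation_consistent_with_refit(self):
        x, y = self._planted(seed=6)
        full = PLSDiscriminant(n_components=4).fit(x, y)
        two = PLSDiscriminant(n_components=2).fit(x, y)
        assert np.allclose(full.transform(x, n_components=2), two.transform(x), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            PLSDiscriminant(2).fit(np.random.default_rng(0).normal(size=(10, 3)),
                                   np.zeros(10))

    def test_zero_components_rejected(self):
        x, y = self._planted()
        with pytest.raises(ConfigurationError):
            PLSDiscriminant(0).fit(x, y)

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        x, y = self._planted(n=60, seed=7)
        yp = rng.permutation(y)
        accs = []
        for seed in range(5):
            idx = np.random.default_rng(seed).permutation(60)
            tr, te = idx[:40], idx[40:]
            est = PLSDiscriminant(n_components=2).fit(x[tr], yp[tr])
            accs.append(np.mean(est.predict(x[te]) == yp[te]))
        assert 0.2 < np.mean(accs) < 0.8


class TestVip:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(0)
        for seed in range(3):
            x = np.random.default_rng(seed).normal(size=(30, 12))
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            model = fit_plsda(x, y, n_components=3)
            v = vip(model)
            assert np.mean(v.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-6)

    def test_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 8))
        x[:, 3] += 2.5 * y
        model = fit_plsda(x, y, n_components=2)
        assert vip(model).idxmax() == 3

    def test_identical_features_all_unit_vip(self):
        col = np.random.default_rng(2).normal(size=30)
        y = (col > 0).astype(int)
        x = np.column_stack([col] * 4)
        model = fit_plsda(x, y, n_components=1)
        assert np.allclose(vip(model).to_numpy(), 1.0, atol=1e-8)

    def test_pca_model_rejected(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(10, 4)), 2)
        with pytest.raises(ContractError):
            vip(model)


class TestChooseComponents:
    def test_forced_single_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 5))
        y = np.repeat([0, 1], 15)
        assert choose_components_cv(x, y, max_components=1, repeats=2) == 1

    def test_noiseless_signal_ties_to_one_component(self):
        # LV1 separates perfectly, so every count ties at zero error and
        # the tie rule returns the most parsimonious one
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 25)
        x = rng.normal(size=(50, 5)) * 0.01
        x[:, 0] = y.astype(float)
        assert choose_components_cv(x, y, max_components=4, repeats=3) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_error_recomputation(self, seed):
        """The returned count is the smallest argmin of the mean balanced
        CV error, recomputed here from scratch."""
        from sklearn.model_selection import RepeatedStratifiedKFold

        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], 25)
        x = rng.normal(size=(50, 8))
        x[:, 0] += 2 * y
        cv = RepeatedStratifiedKFold(n_splits=5, n_repeats=3, random_state=seed)
        errs = np.zeros(4)
        n_folds = 0
        for tr, te in cv.split(x, y):
            est = PLSDiscriminant(n_components=4).fit(x[tr], y[tr])
            for k in range(1, 5):
                pred = est.predict(x[te], n_components=k)
                errs[k - 1] += np.mean([np.mean(pred[y[te] == c] != c) for c in (0, 1)])
            n_folds += 1
        expected = int(np.argmin(np.round(errs / n_folds, 12)) + 1)
        assert choose_components_cv(x, y, max_components=4, repeats=3, seed=seed) == expected

    def test_folds_exceeding_class_size_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 4))
        y = np.repeat([0, 1], 4)
        with pytest.raises(ConfigurationError):
            choose_components_cv(x, y, folds=5)
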