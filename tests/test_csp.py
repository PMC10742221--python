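import numpy as np
import pytest
import scipy.linalg

from skillstate import csp
from skillstate.io import ValidationError
from skillstate.microstate import Segmentation


def spd(n, seed):
    A = np.random.default_rng(seed).standard_normal((n, n))
    return A @ A.T + 1e-3 * np.eye(n)


class TestClassScatter:
    def test_orthonormal_columns_give_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((10, 4)))
        np.testing.assert_allclose(csp.class_scatter([q]), np.eye(4),
                                   atol=1e-12)

    def test_scalar_example(self):
        assert csp.class_scatter([np.array([[1.0], [2.0]])])[0, 0] == 5.0

    def test_sample_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 6))
        np.testing.assert_allclose(
            csp.class_scatter([X]), csp.class_scatter([X[::-1]]), atol=1e-12
        )


class TestMicrostateCondition:
    def _seg(self, labels):
        labels = np.asarray(labels)
        return Segmentation(labels, np.ones_like(labels))

    def test_all_samples_in_state_is_identity(self, rng):
        X = rng.standard_normal((20, 4))
        out = csp.microstate_condition([X], [self._seg([2] * 20)], state=2)
        np.testing.assert_array_equal(out[0], X)

    def test_alternating_labels_keep_half(self, rng):
        X = rng.standard_normal((20, 4))
        seg = self._seg([2, 4] * 10)
        out = csp.microstate_condition([X], [seg], state=4)
        assert out[0].shape == (10, 4)
        np.testing.assert_array_equal(out[0], X[1::2])

    def test_absent_state_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValidationError):
            csp.microstate_condition([X], [self._seg([0] * 10)], state=7)

    def test_auto_uses_first_active_state(self, rng):
        X = rng.standard_normal((10, 4))
        seg = self._seg([3] * 4 + [1] * 6)
        out = csp.microstate_condition([X], [seg], state="auto")
        assert out[0].shape == (4, 4)


class TestRegularizedCSP:
    def test_diagonal_closed_form(self):
        model = csp.fit_regularized_csp(np.diag([4.0, 1.0]), np.eye(2),
                                        alpha=0.0)
        np.testing.assert_allclose(np.abs(model.filters1[:, 0]), [1, 0],
                                   atol=1e-12)
        assert model.eigvals1[0] == pytest.approx(4.0)

    def test_equal_covariances_give_unit_eigenvalues(self):
        C = spd(5, 0)
        model = csp.fit_regularized_csp(C, C, alpha=0.0)
        np.testing.assert_allclose(model.eigvals1, 1.0, atol=1e-9)

    def test_matches_dense_generalized_eigensolver(self):
        """Filters/eigenvalues of (C2+aI)^-1 C1 agree with scipy's dense
        nonsymmetric solve after sign/scale alignment (1e-8)."""
        for seed in range(5):
            C1, C2 = spd(6, seed), spd(6, 100 + seed)
            model = csp.fit_regularized_csp(C1, C2, alpha=0.1)
            w, v = scipy.linalg.eig(
                np.linalg.inv(C2 + 0.1 * np.eye(6)) @ C1
            )
            order = np.argsort(w.real)[::-1]
            v = v[:, order].real
            v /= np.linalg.norm(v, axis=0)
            align = np.abs(np.sum(v * model.filters1, axis=0))
            np.testing.assert_allclose(align, 1.0, atol=1e-8)
            np.testing.assert_allclose(
                model.eigvals1, np.sort(w.real)[::-1], atol=1e-8
            )

    def test_eigenvalue_is_projected_variance_ratio(self):
        C1, C2 = spd(6, 1), spd(6, 2)
        model = csp.fit_regularized_csp(C1, C2, alpha=0.1)
        w0 = model.filters1[:, 0]
        ratio = (w0 @ C1 @ w0) / (w0 @ (C2 + 0.1 * np.eye(6)) @ w0)
        assert ratio == pytest.approx(model.eigvals1[0], rel=1e-9)

    def test_asymmetric_input_rejected(self):
        C = spd(4, 3)
        C[0, 1] += 1.0
        with pytest.raises(ValidationError):
            csp.fit_regularized_csp(C, np.eye(4))

    def test_filters_unit_norm_sign_fixed(self):
        model = csp.fit_regularized_csp(spd(5, 4), spd(5, 5))
        np.testing.assert_allclose(
            np.linalg.norm(model.filters1, axis=0), 1.0
        )
        for col in model.filters1.T:
            assert col[np.abs(col).argmax()] > 0


class TestFeatures:
    def test_whitened_projections_give_zero_features(self):
        model = csp.fit_regularized_csp(np.eye(3), np.eye(3), alpha=0.0)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20000, 3))
        X /= X.std(axis=0)  # unit variance along every direction
        f = csp.csp_features(X, model, n_pairs=1)
        np.testing.assert_allclose(f, 0.0, atol=0.05)

    def test_scaling_adds_2logc(self, rng):
        model = csp.fit_regularized_csp(spd(4, 6), spd(4, 7))
        X = rng.standard_normal((100, 4))
        f1 = csp.csp_features(X, model)
        f2 = csp.csp_features(3.0 * X, model)
        np.testing.assert_allclose(f2 - f1, 2 * np.log(3.0), atol=1e-9)

    def test_group_separation_at_high_snr(self, rng):
        """Epochs dominated by different spatial directions separate by
        >= 1 pooled SD on the leading CSP feature."""
        d1 = np.array([1.0, 0, 0, 0])
        d2 = np.array([0, 1.0, 0, 0])
        eps1 = [np.outer(rng.standard_normal(50), d1)
                + 0.05 * rng.standard_normal((50, 4)) for _ in range(20)]
        eps2 = [np.outer(rng.standard_normal(50), d2)
                + 0.05 * rng.standard_normal((50, 4)) for _ in range(20)]
        model = csp.fit_regularized_csp(
            csp.class_scatter(eps1), csp.class_scatter(eps2)
        )
        f1 = np.array([csp.csp_features(e, model)[0] for e in eps1])
        f2 = np.array([csp.csp_features(e, model)[0] for e in eps2])
        pooled = np.sqrt((f1.var() + f2.var()) / 2)
        assert abs(f1.mean() - f2.mean()) >= pooled


class TestLDA:
    def test_separated_clouds_train_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(8, 1, (30, 2))])
        y = ["a"] * 30 + ["b"] * 30
        model = csp.lda_fit(X, y)
        assert (csp.lda_predict(model, X) == np.array(y)).mean() == 1.0

    def test_identical_distributions_at_chance(self, rng):
        from sklearn.model_selection import cross_val_score
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((200, 4))
        y = np.array([0, 1] * 100)
        acc = cross_val_score(
            LinearDiscriminantAnalysis(), X, y, cv=10
        ).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_zero_variance_feature_with_shrinkage(self):
        X = np.array([[0.0, 1], [0, 2], [0, 3], [0, 4]])
        y = ["a", "a", "b", "b"]
        model = csp.lda_fit(X, y, shrinkage="auto")
        assert np.isfinite(model.weights).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            csp.lda_fit(np.zeros((4, 2)), ["a"] * 4)


class TestCrossValidation:
    def _epochs(self, rng, n_per_class=12):
        d1 = np.array([1.0, 0, 0])
        d2 = np.array([0, 1.0, 0])
        eps, labels = [], []
        for d, lbl in ((d1, "expert"), (d2, "novice")):
            for _ in range(n_per_class):
                eps.append(np.outer(rng.standard_normal(40), d)
                           + 0.05 * rng.standard_normal((40, 3)))
                labels.append(lbl)
        return eps, labels

    def test_separable_epochs_high_accuracy(self, rng):
        eps, labels = self._epochs(rng)
        rep = csp.crossvalidate_csp_lda(eps, labels, folds=4, seed=0)
        assert rep.accuracy >= 0.95

    def test_too_many_folds_rejected(self, rng):
        eps, labels = self._epochs(rng, n_per_class=3)
        with pytest.raises(ValidationError):
            csp.crossvalidate_csp_lda(eps, labels, folds=50)


class TestKappa:
    @pytest.mark.parametrize("conf,expected", [
        ([[50, 0], [0, 50]], 1.0),
        ([[25, 25], [25, 25]], 0.0),
        ([[30, 10], [10, 30]], 0.5),
    ])
    def test_reference_values(self, conf, expected):
        assert csp.kappa(np.array(conf)) == pytest.approx(expected)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(50):
            y1 = rng.integers(0, 2, 40)
            y2 = rng.integers(0, 2, 40)
            tp = int(((y1 == 1) & (y2 == 1)).sum())
            fp = int(((y1 == 0) & (y2 == 1)).sum())
            fn = int(((y1 == 1) & (y2 == 0)).sum())
            tn = int(((y1 == 0) & (y2 == 0)).sum())
            expected = cohen_kappa_score(y1, y2)
            assert csp.kappa([[tp, fp], [fn, tn]]) == pytest.approx(expected)
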