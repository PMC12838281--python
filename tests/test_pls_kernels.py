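"""NIPALS PLS, the LDA head, the kernel registry, PLS-SVM heads and the
multiple-kernel SVM."""

import numpy as np
import pytest

from blendeeg import (
    KernelSpec,
    dkl_svm_fit,
    dkl_svm_predict,
    gram_matrix,
    kernel_eval,
    pls_fit,
    pls_lda_fit,
    pls_lda_predict,
    pls_predict,
    pls_svm_fit,
    pls_svm_predict,
    pls_transform,
)


class TestPLS:
    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        model = pls_fit(X, y, 3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        expect = Xc.T @ yc
        expect /= np.linalg.norm(expect)
        assert np.allclose(model.W[:, 0], expect, atol=1e-12)

    def test_unit_norm_weights_and_orthogonal_scores(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        model = pls_fit(X, y, 6)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10)
        G = model.S.T @ model.S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        model = pls_fit(X, y, 10)
        A = np.column_stack([np.ones(30), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(pls_predict(model, X).ravel() - A @ ols).max() < 1e-6

    def test_transform_reproduces_training_scores(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        model = pls_fit(X, y, 4)
        assert np.abs(pls_transform(model, X) - model.S).max() < 1e-10

    def test_deflation_shrinks_frobenius_norm(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        Xc = X - X.mean(axis=0)
        prev = np.linalg.norm(Xc)
        for H in (1, 3, 5):
            model = pls_fit(X, y, H)
            resid = Xc - model.S @ model.K.T
            assert np.linalg.norm(resid) < prev

    def test_rank_exhaustion_truncates_with_warning(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((20, 2))
        X = np.column_stack([base, base @ rng.standard_normal((2, 4))])  # rank 2
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="rank"):
            model = pls_fit(X, y, 6)
        assert model.n_components <= 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pls_fit(np.ones((10, 3)), np.arange(10.0), 2)

    def test_multiclass_onehot_response(self):
        rng = np.random.default_rng(6)
        y = np.array([0, 1, 2] * 10)
        X = rng.standard_normal((30, 8)) + y[:, None]
        onehot = (y[:, None] == np.arange(3)[None, :]).astype(float)
        model = pls_fit(X, onehot, 4)
        assert model.v.shape == (4, 3)
        assert model.beta.shape == (8, 3)


class TestPLSLDA:
    def test_separated_gaussians_high_accuracy(self):
        """Two well-separated 50-D Gaussian classes, n=60: near-perfect
        CV accuracy (the Bayes rule of the generating model is ~1)."""
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.standard_normal((30, 50)), rng.standard_normal((30, 50)) + 1.0]
        )
        y = np.array([0] * 30 + [1] * 30)
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            model = pls_lda_fit(X[tr], y[tr], n_components=5)
            accs.append(np.mean(pls_lda_predict(model, X[te]) == y[te]))
        assert np.mean(accs) >= 0.95

    def test_symmetric_classes_uniform_posterior(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 4))
        y = np.array([0, 1] * 100)  # labels independent of X, equal priors
        model = pls_lda_fit(X, y, n_components=2)
        _, post = pls_lda_predict(model, np.zeros((1, 4)), return_posterior=True)
        assert np.allclose(post[0], 0.5, atol=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pls_lda_fit(np.random.default_rng(0).standard_normal((10, 3)),
                        np.zeros(10, dtype=int))


class TestKernels:
    def test_polynomial_example(self):
        # s_i . s_j = 1, d = 2 -> (1 + 1)^2 = 4
        assert kernel_eval(KernelSpec("polynomial", degree=2),
                           np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 4.0

    def test_laplacian_identical_points(self):
        s = np.array([0.3, -0.7])
        assert kernel_eval(KernelSpec("laplacian", sigma=2.0), s, s) == 1.0

    def test_linear_gram_of_orthonormal_basis_is_identity(self):
        G = gram_matrix(KernelSpec("linear"), np.eye(4))
        assert np.allclose(G, np.eye(4))

    def test_bessel_unit_at_zero_distance_and_decays(self):
        spec = KernelSpec("bessel", sigma=1.0, order=0)
        s = np.array([1.0, 2.0])
        assert kernel_eval(spec, s, s) == pytest.approx(1.0)
        far = kernel_eval(spec, s, s + 10.0)
        assert abs(far) < 1.0

    def test_gram_symmetry_all_kernels(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((12, 3))
        for spec in (
            KernelSpec("polynomial", degree=3),
            KernelSpec("laplacian", sigma=0.5),
            KernelSpec("linear"),
            KernelSpec("spline"),
            KernelSpec("bessel", sigma=1.0),
        ):
            G = gram_matrix(spec, A)
            assert np.abs(G - G.T).max() < 1e-12

    def test_linear_and_polynomial_grams_psd(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((15, 4))
        for spec in (KernelSpec("linear"), KernelSpec("polynomial", degree=2)):
            vals = np.linalg.eigvalsh(gram_matrix(spec, A))
            assert vals.min() >= -1e-8

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            KernelSpec("laplacian", sigma=0.0)
        with pytest.raises(ValueError):
            KernelSpec("rbfish")
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("linear"), np.ones(2), np.ones(3))


class TestPLSSVM:
    def test_linear_kernel_separable_training_accuracy(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.3, (20, 5)), rng.normal(4, 0.3, (20, 5))])
        y = np.array([0] * 20 + [1] * 20)
        model = pls_svm_fit(X, y, n_components=3, spec=KernelSpec("linear"))
        assert (pls_svm_predict(model, X) == y).all()

    def test_polynomial_kernel_solves_xor(self):
        """XOR corners (replicated with slight jitter) are separable by a
        degree-2 polynomial kernel but not linearly."""
        rng = np.random.default_rng(12)
        corners = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.05, (10, 2)) for c in corners])
        y = np.array([0] * 20 + [1] * 20)
        model = pls_svm_fit(
            X, y, n_components=2, spec=KernelSpec("polynomial", degree=2)
        )
        assert np.mean(pls_svm_predict(model, X) == y) == 1.0

    def test_duplicate_training_point_stable_prediction(self):
        """Duplicating one training point leaves toy predictions
        unchanged (weighting consistency of the soft-margin dual)."""
        X = np.array([[0.0, 0], [0.2, 0], [0.1, 0.2], [3.0, 3], [3.2, 3], [3.1, 3.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        probe = np.array([[0.5, 0.5], [2.5, 2.5], [1.5, 1.5]])
        m1 = pls_svm_fit(X, y, n_components=2, spec=KernelSpec("linear"))
        m2 = pls_svm_fit(np.vstack([X, X[:1]]), np.append(y, 0),
                         n_components=2, spec=KernelSpec("linear"))
        assert np.array_equal(pls_svm_predict(m1, probe), pls_svm_predict(m2, probe))

    def test_three_class_one_vs_rest(self):
        rng = np.random.default_rng(13)
        y = np.array([0, 1, 2] * 20)
        X = rng.normal(0, 0.4, (60, 4)) + 3.0 * y[:, None]
        model = pls_svm_fit(X, y, n_components=3,
                            spec=KernelSpec("polynomial", degree=2))
        assert np.mean(pls_svm_predict(model, X) == y) > 0.95


class TestDKLSVM:
    def test_single_kernel_reduces_to_plain_kernel_svm(self):
        from blendeeg.classifiers_pls_kernels import KernelSVM

        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(3, 1, (25, 3))])
        y = np.array([0] * 25 + [1] * 25)
        spec = KernelSpec("laplacian", sigma=2.0)
        model = dkl_svm_fit(X, y, [spec])
        direct = KernelSVM(C=1.0).fit(gram_matrix(spec, X), y)
        probe = rng.normal(1.5, 1, (20, 3))
        assert np.array_equal(
            dkl_svm_predict(model, probe),
            direct.predict(gram_matrix(spec, probe, X)),
        )
        assert model.weights[0] == 1.0

    def test_weights_on_simplex(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((40, 4))
        y = np.array([0, 1] * 20)
        model = dkl_svm_fit(
            X, y,
            [KernelSpec("linear"), KernelSpec("polynomial", degree=2),
             KernelSpec("laplacian", sigma=1.0)],
        )
        assert (model.weights >= 0).all()
        assert abs(model.weights.sum() - 1.0) < 1e-9

    def test_separating_kernel_dominates(self):
        """XOR geometry: a degree-2 polynomial kernel separates, the
        linear kernel cannot — its weight should win in median over seeds."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            corners = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
            X = np.vstack([c + rng.normal(0, 0.05, (8, 2)) for c in corners])
            y = np.array([0] * 16 + [1] * 16)
            model = dkl_svm_fit(
                X, y, [KernelSpec("polynomial", degree=2), KernelSpec("linear")]
            )
            if model.weights[0] > model.weights[1]:
                wins += 1
        assert wins >= 3

    def test_empty_kernel_list_rejected(self):
        with pytest.raises(ValueError):
            dkl_svm_fit(np.ones((4, 2)), np.array([0, 0, 1, 1]), [])
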