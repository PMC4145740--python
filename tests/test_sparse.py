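"""OMP solver, kernels, and the SRC/KSRC classifiers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import OrthogonalMatchingPursuit

from snosparse.sparse import (
    KernelSparseRepresentationClassifier,
    KernelSpec,
    SparseRepresentationClassifier,
    gram_matrix,
    kernel_vector,
    ksrc_classify,
    load_model,
    masked_residuals,
    omp,
    save_model,
    src_classify,
)


def _random_dictionary(rng, d, n):
    A = rng.normal(size=(d, n))
    return A / np.linalg.norm(A, axis=0)


class TestOMP:
    def test_exact_atom_match_recovers_single_support(self, rng):
        A = _random_dictionary(rng, 8, 12)
        solution = omp(A, A[:, 5], k=3)
        assert solution.support.tolist() == [5]
        assert solution.residual_norm < 1e-10
        assert solution.alpha[5] == pytest.approx(1.0)

    def test_orthogonal_target_selects_nothing(self):
        A = np.eye(4)[:, :2]  # columns e1, e2
        b = np.array([0.0, 0.0, 1.0, 0.0])
        solution = omp(A, b, k=2)
        assert solution.support.size == 0
        assert solution.residual_norm == pytest.approx(np.linalg.norm(b))
        assert np.all(solution.alpha == 0.0)

    def test_residual_norm_non_increasing(self, rng):
        for _ in range(20):
            A = _random_dictionary(rng, 6, 15)
            b = rng.normal(size=6)
            solution = omp(A, b, k=5)
            diffs = np.diff(solution.residual_norms)
            assert np.all(diffs <= 1e-10)

    def test_matches_exhaustive_search_on_planted_systems(self, rng):
        from snosparse.synthetic import make_low_coherence_dictionary

        hits = 0
        for _ in range(20):
            A = make_low_coherence_dictionary(rng, 6, 10, target=0.30, max_iter=500)
            support = rng.choice(10, size=2, replace=False)
            coefs = rng.uniform(0.5, 1.5, 2) * rng.choice([-1, 1], 2)
            b = A[:, support] @ coefs
            solution = omp(A, b, k=2)
            best = min(
                np.linalg.norm(b - A[:, list(s)] @ np.linalg.lstsq(A[:, list(s)], b, rcond=None)[0])
                for s in itertools.combinations(range(10), 2)
            )
            if set(solution.support) == set(support):
                hits += 1
                assert solution.residual_norm <= best + 1e-6
        assert hits >= 18  # low-coherence planted systems are recoverable

    def test_agrees_with_sklearn_omp(self, rng):
        A = _random_dictionary(rng, 20, 30)
        b = A[:, [3, 17]] @ np.array([1.0, -0.7])
        ours = omp(A, b, k=2)
        reference = OrthogonalMatchingPursuit(n_nonzero_coefs=2, fit_intercept=False)
        reference.fit(A, b)
        np.testing.assert_allclose(ours.alpha, reference.coef_, atol=1e-8)

    def test_duplicate_columns_handled_gracefully(self):
        # a column dependent on the selected set is orthogonal to the
        # residual, so OMP never re-selects it and terminates cleanly
        column = np.array([1.0, 1.0, 0.0])
        A = np.column_stack([column, column, np.array([0.0, 0.0, 1.0])])
        b = np.array([2.0, 2.0, 3.0])
        solution = omp(A, b, k=3)
        assert solution.residual_norm < 1e-10
        assert solution.support.size == 2
        assert 1 not in solution.support  # the duplicate is never picked

    def test_invalid_sparsity_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 1"):
            omp(np.eye(3), np.ones(3), k=0)

    def test_eps_stops_early(self, rng):
        A = _random_dictionary(rng, 6, 10)
        b = A[:, 2] * 3.0
        solution = omp(A, b, k=5, eps=1e-3)
        assert solution.support.size == 1


class TestKernels:
    def test_laplacian_gram_unit_diagonal_and_symmetry(self, rng):
        X = rng.normal(size=(15, 4))
        K = gram_matrix(X, KernelSpec(delta=2.0))
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)
        assert np.all(K > 0) and np.all(K <= 1.0)

    def test_points_at_distance_delta_give_inverse_e(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        K = gram_matrix(X, KernelSpec(delta=5.0))
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_l1_metric_uses_manhattan_distance(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        K = gram_matrix(X, KernelSpec(delta=2.0, metric="l1"))
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_positive_semidefinite_up_to_roundoff(self, rng):
        for _ in range(20):
            X = rng.normal(size=(rng.integers(5, 15), rng.integers(2, 6)))
            K = gram_matrix(X, KernelSpec(delta=float(rng.uniform(0.5, 5.0))))
            eigenvalues = np.linalg.eigvalsh(K)
            assert eigenvalues.min() >= -1e-8

    def test_kernel_vector_matches_gram_column(self, rng):
        X = rng.normal(size=(10, 3))
        spec = KernelSpec(delta=1.5)
        K = gram_matrix(X, spec)
        np.testing.assert_allclose(kernel_vector(X, X[4], spec), K[:, 4])

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            KernelSpec(delta=0.0)

    def test_linear_kernel_is_inner_product(self, rng):
        X = rng.normal(size=(6, 3))
        np.testing.assert_allclose(gram_matrix(X, KernelSpec(kind="linear")), X @ X.T)


def test_masked_coefficients_sum_to_full_alpha(rng):
    # the per-class masks partition the coefficient vector exactly
    n, n_classes = 12, 3
    alpha = rng.normal(size=n)
    class_index = rng.integers(0, n_classes, n)
    total = np.zeros(n)
    for k in range(n_classes):
        total += np.where(class_index == k, alpha, 0.0)
    np.testing.assert_array_equal(total, alpha)
    # and masked_residuals evaluates ||b - A alpha_k|| for each mask
    A = rng.normal(size=(5, n))
    b = rng.normal(size=5)
    res = masked_residuals(A, b, alpha, class_index, n_classes)
    expected = [
        np.linalg.norm(b - A @ np.where(class_index == k, alpha, 0.0))
        for k in range(n_classes)
    ]
    np.testing.assert_allclose(res, expected)


class TestSRC:
    def test_training_sample_classified_to_its_class(self, rng):
        X = rng.normal(size=(10, 6))
        y = np.array([0] * 5 + [1] * 5)
        predicted, residuals = src_classify(X, y, X[7], k=3)
        assert predicted == 1
        assert residuals[1] < 1e-10

    def test_orthogonal_columns_pick_max_projection_class(self):
        X = np.eye(4)  # four orthonormal training samples
        y = np.array([0, 0, 1, 1])
        target = np.array([0.1, 0.0, 2.0, 0.0])
        predicted, _ = src_classify(X, y, target, k=1, normalize=False)
        assert predicted == 1  # column 2 has the largest projection

    def test_decision_matches_direct_rule_evaluation(self, rng):
        # 2-class 6-sample toy: compute alpha with an independent solver,
        # then apply the masked-residual argmin rule with plain numpy
        X = rng.normal(size=(6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])
        target = rng.normal(size=4)
        clf = SparseRepresentationClassifier(sparsity=3, normalize=True).fit(X, y)
        predicted = clf.predict(target.reshape(1, -1))[0]

        D = X.T / np.linalg.norm(X.T, axis=0)
        reference = OrthogonalMatchingPursuit(n_nonzero_coefs=3, fit_intercept=False)
        alpha = reference.fit(D, target).coef_
        res = [
            np.linalg.norm(target - D @ np.where(y == k, alpha, 0.0)) for k in (0, 1)
        ]
        assert predicted == int(np.argmin(res))

    def test_residual_tie_breaks_to_lowest_class(self):
        X = np.eye(2)
        y = np.array([0, 1])
        clf = SparseRepresentationClassifier(sparsity=1, normalize=False).fit(X, y)
        # orthogonal to both training samples: zero coefficients, equal residuals
        prediction = clf.predict(np.zeros((1, 2)))
        assert prediction[0] == 0


class TestKSRC:
    def test_training_sample_classified_to_its_class(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.array([0] * 6 + [1] * 6)
        clf = KernelSparseRepresentationClassifier(delta=2.0, sparsity=3).fit(X, y)
        assert clf.predict(X[9].reshape(1, -1))[0] == 1
        assert clf.residuals(X[9].reshape(1, -1))[0, 1] < 1e-8

    def test_huge_delta_degenerate_kernel_still_returns_valid_class(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0] * 4 + [1] * 4)
        clf = KernelSparseRepresentationClassifier(delta=1e6, sparsity=2).fit(X, y)
        predictions = clf.predict(rng.normal(size=(5, 3)))
        assert set(predictions) <= {0, 1}

    def test_median_bandwidth_heuristic_resolved_at_fit(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.arange(10) % 2
        clf = KernelSparseRepresentationClassifier(delta="median").fit(X, y)
        from sklearn.metrics import pairwise_distances

        dist = pairwise_distances(X)
        expected = np.median(dist[np.triu_indices(10, k=1)])
        assert clf.delta_ == pytest.approx(expected)

    def test_separated_blobs_match_bruteforce_reimplementation(self):
        # independent straight-line reimplementation of the kernel sparse
        # coding system, using sklearn's OMP as the solver
        rng = np.random.default_rng(0)
        n, d = 40, 5
        X = np.vstack(
            [rng.normal(-2.0, 1.0, (n // 2, d)), rng.normal(2.0, 1.0, (n // 2, d))]
        )
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        shuffle = rng.permutation(n)
        X, y = X[shuffle], y[shuffle]
        X_train, y_train, X_test, y_test = X[:30], y[:30], X[30:], y[30:]

        from sklearn.metrics import pairwise_distances

        dist = pairwise_distances(X_train)
        delta = float(np.median(dist[np.triu_indices(30, k=1)]))

        clf = KernelSparseRepresentationClassifier(delta=delta, sparsity=5)
        clf.fit(X_train, y_train)
        predictions = clf.predict(X_test)
        assert np.mean(predictions == y_test) >= 0.9

        K = np.exp(-dist / delta)
        oracle = []
        for x in X_test:
            b = np.exp(-np.linalg.norm(X_train - x, axis=1) / delta)
            solver = OrthogonalMatchingPursuit(n_nonzero_coefs=5, fit_intercept=False)
            alpha = solver.fit(K, b).coef_
            res = [
                np.linalg.norm(b - K @ np.where(y_train == k, alpha, 0.0))
                for k in (0, 1)
            ]
            oracle.append(int(np.argmin(res)))
        np.testing.assert_array_equal(predictions, oracle)

    def test_linear_kernel_mostly_agrees_with_src_on_unit_norm_data(self):
        # the Gram reformulation changes atom-selection geometry, so exact
        # equality is not expected; on well-separated data decisions agree.
        # class directions are kept non-antipodal: sign-blind sparse coding
        # cannot distinguish x from -x on unit-norm data
        agree, total = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [
                    0.6 * rng.normal(size=(15, 4)) + np.array([3.0, 0.0, 0.0, 0.0]),
                    0.6 * rng.normal(size=(15, 4)) + np.array([0.0, 3.0, 0.0, 0.0]),
                ]
            )
            X = X / np.linalg.norm(X, axis=1, keepdims=True)
            y = np.array([0] * 15 + [1] * 15)
            test = rng.permutation(30)[:10]
            train = np.setdiff1d(np.arange(30), test)
            src = SparseRepresentationClassifier(sparsity=5).fit(X[train], y[train])
            ksrc = KernelSparseRepresentationClassifier(
                kernel="linear", sparsity=5
            ).fit(X[train], y[train])
            pred_src = src.predict(X[test])
            pred_ksrc = ksrc.predict(X[test])
            agree += int(np.sum(pred_src == pred_ksrc))
            total += len(test)
        assert agree / total >= 0.9

    def test_one_shot_wrapper_matches_estimator(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.arange(10) % 2
        target = rng.normal(size=3)
        spec = KernelSpec(delta=2.0)
        predicted, res = ksrc_classify(X, y, target, spec=spec, k=3)
        clf = KernelSparseRepresentationClassifier(delta=2.0, sparsity=3).fit(X, y)
        assert predicted == clf.predict(target.reshape(1, -1))[0]
        np.testing.assert_allclose(res, clf.residuals(target.reshape(1, -1))[0])


class TestEstimatorContract:
    @pytest.mark.parametrize(
        "estimator",
        [
            SparseRepresentationClassifier(sparsity=3),
            KernelSparseRepresentationClassifier(delta=2.0, sparsity=3),
        ],
    )
    def test_clone_and_classes_attribute(self, estimator, rng):
        X = rng.normal(size=(12, 4))
        y = np.arange(12) % 2
        cloned = clone(estimator)
        cloned.fit(X, y)
        assert list(cloned.classes_) == [0, 1]
        assert cloned.predict(X).shape == (12,)
        margins = cloned.decision_function(X)
        assert margins.shape == (12,)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            SparseRepresentationClassifier().fit(rng.normal(size=(5, 2)), np.zeros(5))


class TestPersistence:
    @pytest.mark.parametrize("kind", ["src", "ksrc"])
    def test_round_trip_preserves_predictions(self, kind, tmp_path, rng):
        X = rng.normal(size=(14, 4))
        y = np.arange(14) % 2
        if kind == "src":
            clf = SparseRepresentationClassifier(sparsity=4).fit(X, y)
        else:
            clf = KernelSparseRepresentationClassifier(delta=3.0, sparsity=4).fit(X, y)
        save_model(tmp_path / "model", clf, feature_names=["f1", "f2", "f3", "f4"])
        loaded = load_model(tmp_path / "model")
        X_new = rng.normal(size=(6, 4))
        np.testing.assert_array_equal(loaded.predict(X_new), clf.predict(X_new))
        np.testing.assert_allclose(
            loaded.residuals(X_new), clf.residuals(X_new), atol=1e-10
        )

    def test_config_file_is_key_value_text(self, tmp_path, rng):
        X = rng.normal(size=(8, 3))
        y = np.arange(8) % 2
        clf = KernelSparseRepresentationClassifier(delta=2.5, sparsity=2).fit(X, y)
        save_model(tmp_path / "m", clf)
        config = (tmp_path / "m" / "config.txt").read_text()
        assert "model=ksrc" in config
        assert "delta=2.5" in config
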