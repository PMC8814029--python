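import numpy as np
import pytest

from qclin.classifiers import (
    Backend,
    LabeledDataset,
    Prediction,
    QKSVMReference,
    WeightVector,
    qdc_classify,
    quantum_distance,
    sqksvm_alpha,
    sqksvm_classify,
    sqksvm_decision,
)
from qclin.encoding import Log2NEncoder, normalize_and_pad
from qclin.inner_product import kernel_matrix
from qclin.pipeline import generate_two_class, imbalance_ratio

ENC = Log2NEncoder()


def classical_qdc(train, x, class_a):
    """Brute-force nearest-set rule with plain dot products."""
    v = normalize_and_pad(x)
    best = {}
    for feats, lab in zip(train.features, train.labels):
        d = 1.0 - float(normalize_and_pad(feats) @ v)
        best[lab] = min(best.get(lab, np.inf), d)
    class_b = [c for c in train.classes if c != class_a][0]
    return class_a if best[class_a] <= best[class_b] else class_b


class TestLabeledDataset:
    def test_classes_in_first_appearance_order(self):
        d = LabeledDataset(np.zeros((3, 2)), np.array(["b", "a", "b"]))
        assert d.classes == ["b", "a"]

    def test_minority_maps_to_plus_one(self):
        d = LabeledDataset(np.zeros((3, 2)), np.array([0, 0, 1]))
        np.testing.assert_array_equal(d.signed_labels(), [-1, -1, 1])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((3, 2)), np.array([0, 1]))

    def test_require_two_classes(self):
        with pytest.raises(ValueError, match="two classes"):
            LabeledDataset(np.zeros((2, 2)), np.array([1, 1])).require_two_classes()


class TestQuantumDistance:
    def test_identical_states(self):
        c = ENC.circuit([3.0, 4.0])
        assert quantum_distance(c, c) == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_states(self):
        assert quantum_distance(
            ENC.circuit([1.0, 0.0]), ENC.circuit([0.0, 1.0])
        ) == pytest.approx(1.0, abs=1e-10)

    def test_antipodal_states(self):
        assert quantum_distance(
            ENC.circuit([1.0, 0.0]), ENC.circuit([-1.0, 0.0])
        ) == pytest.approx(2.0, abs=1e-10)


class TestQDC:
    def _toy(self):
        X = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.1, 0.9]])
        y = np.array(["a", "a", "b", "b"])
        return LabeledDataset(X, y)

    def test_training_sample_recovers_own_label(self):
        train = self._toy()
        assert qdc_classify(train, [1.0, 0.0], ENC).label == "a"
        assert qdc_classify(train, [0.0, 1.0], ENC).label == "b"

    def test_tie_resolves_to_class_a(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        train = LabeledDataset(X, np.array(["a", "b"]))
        # test point equidistant from both training states
        pred = qdc_classify(train, [1.0, 1.0], ENC)
        assert pred.label == "a"
        assert pred.score == pytest.approx(0.0, abs=1e-10)

    def test_class_a_override_flips_tie(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        train = LabeledDataset(X, np.array(["a", "b"]))
        assert qdc_classify(train, [1.0, 1.0], ENC, class_a="b").label == "b"

    def test_duplicate_training_sample_is_noop(self, rng):
        train = LabeledDataset(rng.standard_normal((6, 4)), np.array([0, 0, 0, 1, 1, 1]))
        dup = LabeledDataset(
            np.vstack([train.features, train.features[0]]),
            np.append(train.labels, train.labels[0]),
        )
        x = rng.standard_normal(4)
        p1, p2 = qdc_classify(train, x, ENC), qdc_classify(dup, x, ENC)
        assert p1.label == p2.label
        assert p1.score == pytest.approx(p2.score, abs=1e-12)

    def test_empty_class_rejected(self):
        train = LabeledDataset(np.eye(2), np.array(["a", "a"]))
        with pytest.raises(ValueError):
            qdc_classify(train, [1.0, 0.0], ENC)

    def test_matches_classical_oracle_200_draws(self):
        rng = np.random.default_rng(77)
        for trial in range(20):
            data = generate_two_class(12, 4, 1.0, IR=0.4, seed=trial)
            for x in rng.standard_normal((10, 4)):
                pred = qdc_classify(data, x, ENC)
                assert pred.label == classical_qdc(data, x, data.classes[0])


class TestSqksvmAlpha:
    def test_balanced_gives_uniform_weights(self):
        w = sqksvm_alpha([1, 1, -1, -1], 0.5)
        np.testing.assert_array_equal(w.alpha, np.ones(4))

    def test_quarter_imbalance(self):
        w = sqksvm_alpha([+1, +1, +1, -1], 0.25)
        np.testing.assert_allclose(w.alpha, [0.25, 0.25, 0.25, 0.75])

    def test_wisconsin_ratio(self):
        labels = np.array([0] * 63 + [1] * 37)
        w = sqksvm_alpha(labels, 0.37)
        assert set(w.alpha[labels == 0]) == {0.37}
        assert set(w.alpha[labels == 1]) == {1 - 0.37}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sqksvm_alpha([1, 1, 1], 0.5)

    def test_ir_range_validated(self):
        with pytest.raises(ValueError):
            sqksvm_alpha([1, -1], 0.7)

    def test_weight_vector_invariant(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([0.0, 1.0]))


class TestSqksvmClassify:
    def test_all_positive_labels_vote_positive(self):
        w = WeightVector(np.ones(3))
        pred = sqksvm_classify([1, 1, 1], w, [0.2, 0.5, 0.9])
        assert pred.label == 1 and pred.score > 0

    def test_zero_score_maps_to_plus_one(self):
        w = WeightVector(np.ones(2))
        pred = sqksvm_classify([1, -1], w, [0.5, 0.5])
        assert pred.score == pytest.approx(0.0)
        assert pred.label == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sqksvm_decision([1, -1], WeightVector(np.ones(2)), [0.1])

    def test_antisymmetry_under_label_flip(self, rng):
        y = np.array([1, 1, -1, -1, 1])
        w = sqksvm_alpha(y, 0.4)
        k = rng.uniform(0, 1, 5)
        assert sqksvm_decision(y, w, k) == pytest.approx(-sqksvm_decision(-y, w, k))

    def test_matches_bruteforce_oracle_200_draws(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            m = int(rng.integers(3, 12))
            y = rng.choice([-1.0, 1.0], m)
            if len(set(y)) < 2:
                continue
            alpha = rng.uniform(0.05, 1.0, m)
            k = rng.uniform(0, 1, m)
            expected = sum(y[i] * alpha[i] * k[i] for i in range(m))
            got = sqksvm_decision(y, WeightVector(alpha), k)
            assert got == pytest.approx(expected, abs=1e-12)
            assert sqksvm_classify(y, WeightVector(alpha), k).label == (
                1 if expected >= 0 else -1
            )


class TestQKSVMReference:
    def test_separable_toy_perfect_training_accuracy(self):
        X = np.array([[1.0, 0.05], [0.9, 0.1], [0.05, 1.0], [0.1, 0.9]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        K = kernel_matrix(X, X, ENC).entries
        model = QKSVMReference().fit(K, y)
        np.testing.assert_array_equal(model.predict(K), y)

    def test_deterministic_refit(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.sign(rng.standard_normal(10))
        y[0], y[1] = 1.0, -1.0
        K = kernel_matrix(X, X, ENC).entries
        m1 = QKSVMReference().fit(K, y)
        m2 = QKSVMReference().fit(K, y)
        np.testing.assert_array_equal(m1.dual_coef, m2.dual_coef)
        assert m1.intercept == m2.intercept

    def test_matches_qp_dual_oracle(self):
        # independent solve of the soft-margin dual: SLSQP to locate the
        # active set, then an exact KKT linear solve on the free variables
        from scipy.optimize import minimize

        data = generate_two_class(20, 4, 3.0, seed=3)
        y = data.signed_labels()
        K = kernel_matrix(data.features, data.features, ENC).entries
        m, C = len(y), 1.0
        Q = (y[:, None] * y[None, :]) * K

        res = minimize(
            lambda a: 0.5 * a @ Q @ a - a.sum(),
            np.full(m, 0.01),
            jac=lambda a: Q @ a - 1.0,
            bounds=[(0, C)] * m,
            constraints={"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
            method="SLSQP",
            options={"maxiter": 5000, "ftol": 1e-14},
        )
        assert res.success
        alpha = res.x.copy()
        free = (alpha > 1e-5) & (alpha < C - 1e-5)
        alpha[alpha <= 1e-5] = 0.0
        alpha[alpha >= C - 1e-5] = C
        # KKT on the free set: Q_FF a_F + y_F b = 1 - Q_FB a_B ; y_F.a_F = -y_B.a_B
        F = np.where(free)[0]
        B = np.where(~free)[0]
        A = np.zeros((len(F) + 1, len(F) + 1))
        A[: len(F), : len(F)] = Q[np.ix_(F, F)]
        A[: len(F), -1] = y[F]
        A[-1, : len(F)] = y[F]
        rhs = np.concatenate([1.0 - Q[np.ix_(F, B)] @ alpha[B], [-y[B] @ alpha[B]]])
        sol = np.linalg.solve(A, rhs)
        alpha[F], oracle_b = sol[:-1], sol[-1]
        oracle_dec = K @ (alpha * y) + oracle_b

        model = QKSVMReference(C=C).fit(K, y)
        np.testing.assert_allclose(model.decision_function(K), oracle_dec, atol=1e-6)

    def test_indefinite_kernel_repaired_with_warning(self):
        K = np.array([[1.0, 0.99], [0.99, -0.5]])
        with pytest.warns(UserWarning, match="indefinite"):
            QKSVMReference().fit(K, np.array([1.0, -1.0]))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            QKSVMReference().fit(np.ones((2, 3)), [1, -1])


class TestBackend:
    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            Backend(mode="fuzzy")

    def test_exact_overlap_matches_dot(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4)
        dot = float(normalize_and_pad(a) @ normalize_and_pad(b))
        be = Backend()
        assert be.overlap(ENC.circuit(a), ENC.circuit(b)) == pytest.approx(dot, abs=1e-10)

    def test_noisy_backend_contracts_overlap(self, rng):
        a = rng.standard_normal(4)
        c = ENC.circuit(a)
        be = Backend(mode="exact", lam=0.2)
        # self-overlap 1 contracts to (1 - lam)
        assert be.overlap(c, c) == pytest.approx(0.8, abs=1e-10)


class TestSeparationProperty:
    def test_well_separated_data_all_classifiers_auc_high(self):
        from qclin.pipeline import CVConfig, cross_validate

        data = generate_two_class(60, 8, 3.0, IR=0.5, seed=2)
        cfg = CVConfig(n_folds=3, seed=1)
        for clf in ("qdc", "sqksvm", "qksvm-ref"):
            rep = cross_validate(data, clf, "log2n", cfg)
            assert rep.mean_auc >= 0.95, (clf, rep.mean_auc)
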