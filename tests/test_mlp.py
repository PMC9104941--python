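"""Levenberg-Marquardt MLP: splitting, initialization, training, evaluation."""

import numpy as np
import pytest

from radarvitals import features, forward_model as fm, mlp
from radarvitals.errors import InvalidArgumentError, SingleClassError


def cohort_matrix(n=200, mix=0.5, seed=3):
    cohort = fm.simulate_rr_cohort(n, mix, seed=seed)
    X = np.array(
        [
            features.compute_features(s.rr_intervals, s.age, s.gender_code).to_array()
            for s in cohort
        ]
    )
    y = np.array([s.label for s in cohort])
    return X, y


class TestSplit:
    def test_33_examples_split_23_5_5(self):
        tr, va, te = mlp.split_dataset(list(range(33)), seed=0, labels=[0] * 18 + [1] * 15)
        assert (len(tr), len(va), len(te)) == (23, 5, 5)

    def test_deterministic_for_fixed_seed(self):
        a = mlp.split_dataset(list(range(20)), seed=9)
        b = mlp.split_dataset(list(range(20)), seed=9)
        assert a == b

    def test_partition_property(self):
        items = list(range(33))
        tr, va, te = mlp.split_dataset(items, seed=4, labels=[0] * 18 + [1] * 15)
        assert sorted(tr + va + te) == items
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_empty_split_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mlp.split_dataset(list(range(3)), seed=0)


class TestInit:
    def test_parameter_count_is_225(self):
        assert mlp.init_network(seed=0).n_parameters == 225

    def test_same_seed_identical(self):
        a, b = mlp.init_network(seed=5), mlp.init_network(seed=5)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_zero_parameters_give_half_output(self):
        model = mlp.init_network(seed=0)
        model.set_params(np.zeros(model.n_parameters))
        assert np.all(model.forward(np.random.default_rng(0).normal(size=(5, 7))) == 0.5)


class TestGradientAndSteps:
    def test_jacobian_matches_finite_differences(self):
        model = mlp.init_network(input_dim=4, seed=1, layer_sizes=(3, 2, 1))
        rng = np.random.default_rng(0)
        X = rng.normal(size=(11, 4))
        y = rng.integers(0, 2, 11).astype(float)
        r, J = mlp.residuals_and_jacobian(model, X, y)
        grad = J.T @ r
        theta = model.get_params()
        eps = 1e-6
        fd = np.empty_like(theta)
        for i in range(len(theta)):
            for sign, out in ((1, "p"), (-1, "m")):
                t = theta.copy()
                t[i] += sign * eps
                model.set_params(t)
                rr, _ = mlp.residuals_and_jacobian(model, X, y)
                if sign == 1:
                    up = 0.5 * np.sum(rr**2)
                else:
                    dn = 0.5 * np.sum(rr**2)
            fd[i] = (up - dn) / (2 * eps)
        model.set_params(theta)
        assert np.max(np.abs(grad - fd)) / np.max(np.abs(fd)) < 1e-5

    def test_small_damping_approaches_gauss_newton(self, rng):
        J = rng.normal(size=(30, 5)) + np.eye(30, 5)  # well-conditioned
        r = rng.normal(size=30)
        gn = -np.linalg.solve(J.T @ J, J.T @ r)
        lm = mlp.lm_step(J, r, mu=1e-12)
        assert np.allclose(lm, gn, rtol=1e-6)

    def test_large_damping_approaches_gradient_direction(self, rng):
        J = rng.normal(size=(30, 5))
        r = rng.normal(size=30)
        lm = mlp.lm_step(J, r, mu=1e12)
        g = -(J.T @ r)
        cos = np.dot(lm, g) / (np.linalg.norm(lm) * np.linalg.norm(g))
        assert cos >= 0.999

    def test_linear_problem_solved_in_one_accepted_step(self, rng):
        """On a linear-in-parameters model LM reaches least squares at once."""
        A = rng.normal(size=(40, 3))
        b = rng.normal(size=40)
        theta_star, *_ = np.linalg.lstsq(A, b, rcond=None)

        def residual(theta):
            return A @ theta - b, A

        theta, history, _ = mlp.levenberg_marquardt(
            residual, rng.normal(size=3), max_iter=1, mu0=1e-12
        )
        assert np.allclose(theta, theta_star, rtol=1e-6, atol=1e-9)


class TestTraining:
    def test_accepted_step_mse_strictly_decreases(self):
        X, y = cohort_matrix()
        _, history, _ = mlp.train_classifier(X, y, seed=3)
        mses = history.train_mse
        assert all(b < a for a, b in zip(mses, mses[1:]))

    def test_cohort_training_accuracy(self):
        X, y = cohort_matrix(n=200, mix=0.5, seed=3)
        _, _, report = mlp.train_classifier(X, y, seed=3)
        assert report["train_accuracy"] >= 0.9
        assert report["test_accuracy"] >= 0.8

    def test_training_is_deterministic(self):
        X, y = cohort_matrix(n=60, seed=5)
        m1, h1, _ = mlp.train_classifier(X, y, seed=7)
        m2, h2, _ = mlp.train_classifier(X, y, seed=7)
        assert np.array_equal(m1.get_params(), m2.get_params())
        assert h1.train_mse == h2.train_mse

    def test_single_class_refused(self):
        X, y = cohort_matrix(n=20, mix=0.0, seed=1)
        with pytest.raises(SingleClassError):
            mlp.train_classifier(X, y, seed=0)

    def test_history_lengths_consistent(self):
        X, y = cohort_matrix(n=60, seed=5)
        _, history, _ = mlp.train_classifier(X, y, seed=7)
        n = len(history.train_mse)
        assert len(history.val_mse) == len(history.gradient_norm) == len(history.mu) == n
        assert all(m > 0 for m in history.mu)


class TestPredictAndConfusion:
    def test_zero_network_predicts_half(self):
        model = mlp.init_network(seed=0)
        model.set_params(np.zeros(model.n_parameters))
        prob, label = mlp.predict(model, np.zeros(7))
        assert prob[0] == 0.5 and label[0] == 1  # threshold is inclusive

    def test_positive_weight_network_is_monotone(self):
        model = mlp.init_network(seed=0)
        model.set_params(np.abs(model.get_params()))
        x = np.full(7, 0.2)
        lo, _ = mlp.predict(model, x)
        x_hi = x.copy()
        x_hi[2] += 0.5
        hi, _ = mlp.predict(model, x_hi)
        assert hi[0] >= lo[0]

    def test_predict_is_pure(self):
        model = mlp.init_network(seed=1)
        x = np.random.default_rng(0).normal(size=7)
        assert mlp.predict(model, x)[0] == mlp.predict(model, x)[0]

    def test_wrong_dimension_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mlp.predict(mlp.init_network(seed=0), np.zeros(5))

    def test_perfect_predictions(self):
        tn, fp, fn, tp, acc = mlp.confusion_and_accuracy([0, 1, 0, 1], [0, 1, 0, 1])
        assert (fp, fn, acc) == (0, 0, 1.0)

    def test_reported_counts_arithmetic(self):
        """Counts (TN, FP, FN, TP) = (18, 2, 0, 13) give accuracy 31/33."""
        labels = [0] * 20 + [1] * 13
        preds = [0] * 18 + [1] * 2 + [1] * 13
        tn, fp, fn, tp, acc = mlp.confusion_and_accuracy(labels, preds)
        assert (tn, fp, fn, tp) == (18, 2, 0, 13)
        assert acc == pytest.approx(31 / 33)

    def test_class_swap_symmetry(self, rng):
        labels = rng.integers(0, 2, 50)
        preds = rng.integers(0, 2, 50)
        tn, fp, fn, tp, _ = mlp.confusion_and_accuracy(labels, preds)
        tn2, fp2, fn2, tp2, _ = mlp.confusion_and_accuracy(1 - labels, 1 - preds)
        assert (tn2, fp2, fn2, tp2) == (tp, fn, fp, tn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mlp.confusion_and_accuracy([0, 1], [0])


class TestSerialization:
    def test_json_round_trip(self):
        X, y = cohort_matrix(n=60, seed=5)
        model, *_ = mlp.train_classifier(X, y, seed=7)
        clone = mlp.MLPModel.from_json(model.to_json())
        probs_a, _ = mlp.predict(model, X[:5])
        probs_b, _ = mlp.predict(clone, X[:5])
        assert np.allclose(probs_a, probs_b, rtol=1e-12)
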