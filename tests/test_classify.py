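"""Decoder correctness: closed-form LDA, SVM objective, MLP convergence."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from mibci.classify import (
    TrainConfig,
    decision_values,
    fit_lda,
    fit_mlp,
    fit_svm,
    predict,
    svm_primal_objective,
)
from mibci.csp import FeatureMatrix


def feats_from(x, y):
    return FeatureMatrix(values=np.asarray(x, float), labels=np.asarray(y))


def gaussian_two_class(rng, n_per_class=50, dim=4, delta=2.0):
    """Shared-covariance Gaussian classes separated along the first axis."""
    a = rng.standard_normal((dim, dim)) / np.sqrt(dim)
    cov_half = a + np.eye(dim)
    mu1 = np.zeros(dim)
    mu1[0] = delta
    x0 = rng.standard_normal((n_per_class, dim)) @ cov_half.T
    x1 = rng.standard_normal((n_per_class, dim)) @ cov_half.T + mu1
    x = np.vstack([x0, x1])
    y = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    return feats_from(x, y), cov_half @ cov_half.T, mu1


class TestLDA:
    def test_symmetric_isotropic_case_closed_form(self):
        """Means (0,0) and (2,0), isotropic scatter: w along x, boundary x=1."""
        base = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        x = np.vstack([base, base + [2.0, 0.0]])
        y = ["a"] * 4 + ["b"] * 4
        model = fit_lda(feats_from(x, y), positive_label="b")
        w = model.weights
        assert w[0] > 0 and abs(w[1]) < 1e-12
        # decision boundary: w . (1, anything) + b = 0
        assert abs(w[0] * 1.0 + model.bias) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pooled_covariance_solve_oracle(self, seed):
        """Weights equal an independently coded Sigma^-1 (mu1 - mu0)."""
        rng = np.random.default_rng(seed)
        feats, _, _ = gaussian_two_class(rng)
        model = fit_lda(feats, positive_label="pos")
        x, y = feats.values, feats.labels
        x0, x1 = x[y == "neg"], x[y == "pos"]
        s = ((x0 - x0.mean(0)).T @ (x0 - x0.mean(0))
             + (x1 - x1.mean(0)).T @ (x1 - x1.mean(0))) / len(x)
        w_oracle = np.linalg.lstsq(s, x1.mean(0) - x0.mean(0), rcond=None)[0]
        assert np.allclose(model.weights, w_oracle, atol=1e-8)

    def test_agrees_with_sklearn_reference(self):
        """Predictions match scikit-learn's LDA on the same data."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(7)
        feats, _, _ = gaussian_two_class(rng)
        model = fit_lda(feats, positive_label="pos")
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            feats.values, feats.labels
        )
        assert np.array_equal(predict(model, feats), ref.predict(feats.values))

    def test_duplicating_trials_leaves_model_unchanged(self):
        rng = np.random.default_rng(3)
        feats, _, _ = gaussian_two_class(rng)
        dup = feats_from(
            np.vstack([feats.values] * 2), np.concatenate([feats.labels] * 2)
        )
        m1 = fit_lda(feats, positive_label="pos")
        m2 = fit_lda(dup, positive_label="pos")
        assert np.allclose(m1.weights, m2.weights, atol=1e-10)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-10)

    def test_affine_invariance_of_decisions(self):
        """Any invertible affine feature map leaves LDA decisions unchanged."""
        rng = np.random.default_rng(11)
        feats, _, _ = gaussian_two_class(rng)
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        c = rng.standard_normal(4)
        mapped = feats_from(feats.values @ a.T + c, feats.labels)
        d1 = decision_values(fit_lda(feats, positive_label="pos"), feats)
        d2 = decision_values(fit_lda(mapped, positive_label="pos"), mapped)
        assert np.allclose(d1, d2, atol=1e-6)

    def test_singular_covariance_is_error(self):
        x = np.zeros((8, 3))
        x[4:, 0] = 1.0  # only one informative, constant dimension
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_lda(feats_from(x, ["a"] * 4 + ["b"] * 4))

    def test_accuracy_approaches_bayes_rate(self):
        """Shared-covariance Gaussians: test accuracy ~ Phi(Delta/2)."""
        accs, bayes = [], []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            full, cov, mu1 = gaussian_two_class(rng, n_per_class=400)
            x, y = full.values, full.labels
            tr = np.zeros(len(y), bool)
            tr[:200] = tr[400:600] = True  # first half of each class
            model = fit_lda(feats_from(x[tr], y[tr]), positive_label="pos")
            test = feats_from(x[~tr], y[~tr])
            accs.append(np.mean(predict(model, test) == test.labels))
            delta = np.sqrt(mu1 @ np.linalg.solve(cov, mu1))
            bayes.append(norm.cdf(delta / 2))
        assert abs(np.mean(accs) - np.mean(bayes)) < 0.03


class TestSVM:
    def separable(self):
        x = np.array(
            [[-2.0, 0.0], [-3.0, 1.0], [-2.5, -1.0], [2.0, 0.0], [3.0, -1.0], [2.5, 1.0]]
        )
        return feats_from(x, ["a", "a", "a", "b", "b", "b"])

    def test_separable_data_trains_to_perfect_accuracy(self):
        feats = self.separable()
        model = fit_svm(feats, positive_label="b")
        assert np.array_equal(predict(model, feats), feats.labels)

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_dense_qp_oracle(self, seed):
        """Primal hinge objective vs an SLSQP solve of the slack QP."""
        rng = np.random.default_rng(seed)
        x = np.vstack(
            [rng.normal([0, 0], 1, (10, 2)), rng.normal([2, 1], 1, (10, 2))]
        )
        y = np.array(["a"] * 10 + ["b"] * 10)
        y_pm = np.where(y == "b", 1.0, -1.0)
        c = 1.0
        cfg = TrainConfig(svm_c=c, standardize=False, tolerance=1e-8)
        model = fit_svm(feats_from(x, y), cfg, positive_label="b")
        obj_impl = svm_primal_objective(model.weights, model.bias, x, y_pm, c)

        n = len(x)

        def obj(v):
            return 0.5 * v[:2] @ v[:2] + c * v[3:].sum()

        cons = [
            {"type": "ineq",
             "fun": lambda v, i=i: y_pm[i] * (x[i] @ v[:2] + v[2]) - 1 + v[3 + i]}
            for i in range(n)
        ]
        bounds = [(None, None)] * 3 + [(0, None)] * n
        res = minimize(
            obj, np.zeros(3 + n), method="SLSQP", constraints=cons,
            bounds=bounds, options={"maxiter": 1000, "ftol": 1e-12},
        )
        assert res.success
        assert abs(obj_impl - res.fun) < 1e-4

    def test_label_flip_negates_the_model(self):
        rng = np.random.default_rng(5)
        feats, _, _ = gaussian_two_class(rng, n_per_class=20, dim=2)
        cfg = TrainConfig(standardize=False, tolerance=1e-8)
        m_pos = fit_svm(feats, cfg, positive_label="pos")
        m_neg = fit_svm(feats, cfg, positive_label="neg")
        assert np.allclose(m_pos.weights, -m_neg.weights, atol=1e-6)
        assert m_pos.bias == pytest.approx(-m_neg.bias, abs=1e-6)


class TestMLP:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        feats, _, _ = gaussian_two_class(rng, n_per_class=20)
        cfg = TrainConfig(seed=77)
        m1 = fit_mlp(feats, cfg, positive_label="pos")
        m2 = fit_mlp(feats, cfg, positive_label="pos")
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)

    def test_training_reduces_the_loss(self):
        rng = np.random.default_rng(4)
        feats, _, _ = gaussian_two_class(rng, n_per_class=30)
        model = fit_mlp(feats, TrainConfig(seed=0), positive_label="pos")
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_solves_xor_where_linear_models_cannot(self):
        """Four-cluster XOR layout: >90% training accuracy, majority of seeds."""
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]], float)
        x = np.vstack([rng.normal(c, 0.5, (50, 2)) for c in centers])
        y = np.array(["a"] * 100 + ["b"] * 100)
        feats = feats_from(x, y)
        wins = 0
        for seed in range(5):
            cfg = TrainConfig(seed=seed, mlp_epochs=2000)
            model = fit_mlp(feats, cfg, positive_label="b")
            acc = np.mean(predict(model, feats) == y)
            wins += acc > 0.9
        assert wins >= 3
        # the linear baseline is stuck near chance on the same layout
        lda_acc = np.mean(predict(fit_lda(feats, positive_label="b"), feats) == y)
        assert lda_acc < 0.65

    def test_forward_pass_matches_sklearn_probabilities(self):
        """The folded-scaler manual forward pass reproduces sklearn's output."""
        from sklearn.neural_network import MLPClassifier

        rng = np.random.default_rng(8)
        feats, _, _ = gaussian_two_class(rng, n_per_class=25)
        cfg = TrainConfig(seed=1)
        model = fit_mlp(feats, cfg, positive_label="pos")
        mu, sd = feats.values.mean(0), feats.values.std(0)
        net = MLPClassifier(
            hidden_layer_sizes=(10,), activation="relu", solver="sgd",
            alpha=0.0, batch_size=feats.n_trials, learning_rate_init=cfg.mlp_lr,
            momentum=0.0, nesterovs_momentum=False, max_iter=cfg.mlp_epochs,
            shuffle=True, random_state=cfg.seed, tol=cfg.tolerance,
            n_iter_no_change=cfg.mlp_epochs,
        ).fit((feats.values - mu) / sd, (feats.labels == "pos").astype(int))
        p_ref = net.predict_proba((feats.values - mu) / sd)[:, 1]
        p_ours = decision_values(model, feats) + 0.5
        assert np.allclose(p_ours, p_ref, atol=1e-10)


class TestPredict:
    def test_boundary_trial_goes_to_positive_class(self):
        from mibci.classify import LinearModel

        model = LinearModel(
            weights=np.array([1.0, 0.0]), bias=-1.0, kind="lda",
            positive_label="mi", negative_label="rest",
        )
        feats = feats_from([[1.0, 5.0]], ["?"])  # decision value exactly 0
        assert predict(model, feats)[0] == "mi"

    def test_prediction_order_invariance(self):
        rng = np.random.default_rng(9)
        feats, _, _ = gaussian_two_class(rng, n_per_class=15)
        model = fit_lda(feats, positive_label="pos")
        perm = rng.permutation(feats.n_trials)
        shuffled = feats_from(feats.values[perm], feats.labels[perm])
        assert np.array_equal(
            predict(model, shuffled), predict(model, feats)[perm]
        )

    def test_dimension_mismatch_is_error(self):
        rng = np.random.default_rng(10)
        feats, _, _ = gaussian_two_class(rng, dim=4)
        model = fit_lda(feats, positive_label="pos")
        with pytest.raises(ValueError, match="dimension"):
            predict(model, feats_from(np.zeros((2, 3)), ["a", "b"]))


class TestChanceLevel:
    def test_all_decoders_at_chance_on_shuffled_labels(self):
        """Label-shuffled Gaussian features: every decoder near 50%."""
        means = {"lda": [], "svm": [], "mlp": []}
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            train, _, _ = gaussian_two_class(rng, n_per_class=30)
            test, _, _ = gaussian_two_class(rng, n_per_class=30)
            y_shuf = rng.permutation(train.labels)
            train_s = feats_from(train.values, y_shuf)
            cfg = TrainConfig(seed=seed)
            models = {
                "lda": fit_lda(train_s, positive_label="pos"),
                "svm": fit_svm(train_s, cfg, positive_label="pos"),
                "mlp": fit_mlp(train_s, cfg, positive_label="pos"),
            }
            y_test = rng.permutation(test.labels)
            for name, model in models.items():
                means[name].append(np.mean(predict(model, test) == y_test))
        for name, accs in means.items():
            assert abs(np.mean(accs) - 0.5) < 0.05, name
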