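"""The three decoders behind one train/predict contract.

All three operate on CSP log-variance features and a binary label set:

* LDA — Fisher's linear discriminant with equal priors and no shrinkage,
  computed in closed form: w = Sigma^-1 (mu_pos - mu_neg) with the pooled
  within-class covariance Sigma, and a bias that puts the boundary at the
  midpoint of the projected class means.
* linear SVM — L2-regularized hinge loss with penalty C (default 1.0) and an
  unpenalized intercept.
* MLP — one hidden layer of ten ReLU units, sigmoid output, trained by plain
  stochastic gradient descent on the cross-entropy loss (learning rate 0.01,
  full batch, 200 epochs by default), seeded for determinism.

SVM and MLP features are z-scored on the training data for optimizer
conditioning; the standardization is folded back into the returned model
parameters so every model maps raw features to decisions.  LDA is affine
invariant and gets raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .csp import FeatureMatrix

CLASSIFIER_NAMES = ("lda", "mlp", "svm")


@dataclass
class TrainConfig:
    """Optimizer settings; the defaults are the study configuration."""

    svm_c: float = 1.0
    mlp_lr: float = 0.01
    mlp_epochs: int = 200
    mlp_batch: int | None = None  # None = full batch
    seed: int = 0
    tolerance: float = 1e-6
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.mlp_lr <= 0:
            raise ValueError("mlp_lr must be positive")


@dataclass
class LinearModel:
    """Affine decision rule: predict positive iff weights . x + bias >= 0."""

    weights: np.ndarray
    bias: float
    kind: str  # "lda" or "svm"
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ValueError("model parameters must be finite")


@dataclass
class MLPModel:
    """One-hidden-layer ReLU network with a sigmoid output unit."""

    hidden_weights: np.ndarray  # n_features x 10
    hidden_bias: np.ndarray  # 10
    output_weights: np.ndarray  # 10
    output_bias: float
    seed: int
    positive_label: str
    negative_label: str
    loss_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hidden_weights.shape[1] != 10:
            raise ValueError("hidden layer width must be 10")
        for p in (self.hidden_weights, self.hidden_bias, self.output_weights):
            if not np.all(np.isfinite(p)):
                raise ValueError("model parameters must be finite")


def _split_labels(feats: FeatureMatrix, positive_label: str | None) -> tuple[str, str]:
    classes = sorted(set(map(str, feats.labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes}")
    negative_label = classes[0] if classes[1] == positive_label else classes[1]
    return positive_label, negative_label


def _binary_targets(feats: FeatureMatrix, positive_label: str) -> np.ndarray:
    return (feats.labels.astype(str) == positive_label).astype(int)


def fit_lda(feats: FeatureMatrix, positive_label: str | None = None) -> LinearModel:
    """Closed-form Fisher LDA with equal priors and no regularization."""
    pos, neg = _split_labels(feats, positive_label)
    x = feats.values
    y = _binary_targets(feats, pos)
    mu0, mu1 = x[y == 0].mean(axis=0), x[y == 1].mean(axis=0)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 trials per class to pool a covariance")
    x0c = x[y == 0] - mu0
    x1c = x[y == 1] - mu1
    # biased pooled covariance (divisor n): a sufficient statistic, so the
    # model is invariant under duplicating the training set
    sigma = (x0c.T @ x0c + x1c.T @ x1c) / (n0 + n1)
    if np.linalg.cond(sigma) > 1e12:
        raise np.linalg.LinAlgError(
            "singular pooled covariance: use a longer window or fewer CSP "
            "features"
        )
    w = np.linalg.solve(sigma, mu1 - mu0)
    b = -float(w @ (mu0 + mu1)) / 2.0
    return LinearModel(weights=w, bias=b, kind="lda", positive_label=pos, negative_label=neg)


def _fit_scaler(x: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def fit_svm(
    feats: FeatureMatrix,
    cfg: TrainConfig | None = None,
    positive_label: str | None = None,
) -> LinearModel:
    """Linear-kernel soft-margin SVM (hinge loss, penalty C, free intercept)."""
    cfg = cfg or TrainConfig()
    pos, neg = _split_labels(feats, positive_label)
    y = _binary_targets(feats, pos)
    mu, sd = _fit_scaler(feats.values, cfg.standardize)
    xs = (feats.values - mu) / sd
    svc = SVC(kernel="linear", C=cfg.svm_c, tol=cfg.tolerance)
    svc.fit(xs, y)
    if svc.fit_status_ != 0:
        raise RuntimeError("SVM solver did not converge within its iteration cap")
    w_s = svc.coef_[0]
    b_s = float(svc.intercept_[0])
    # fold the z-scoring back into raw-feature space
    w = w_s / sd
    b = b_s - float((w_s * mu / sd).sum())
    return LinearModel(weights=w, bias=b, kind="svm", positive_label=pos, negative_label=neg)


def svm_primal_objective(
    w: np.ndarray, b: float, x: np.ndarray, y_pm: np.ndarray, c: float
) -> float:
    """0.5 ||w||^2 + C sum hinge — for solver validation and convergence checks."""
    margins = y_pm * (x @ w + b)
    return 0.5 * float(w @ w) + c * float(np.maximum(0.0, 1.0 - margins).sum())


def fit_mlp(
    feats: FeatureMatrix,
    cfg: TrainConfig | None = None,
    positive_label: str | None = None,
) -> MLPModel:
    """Ten-ReLU-unit MLP trained by seeded SGD on cross-entropy."""
    cfg = cfg or TrainConfig()
    pos, neg = _split_labels(feats, positive_label)
    y = _binary_targets(feats, pos)
    mu, sd = _fit_scaler(feats.values, cfg.standardize)
    xs = (feats.values - mu) / sd
    batch = cfg.mlp_batch if cfg.mlp_batch is not None else xs.shape[0]
    net = MLPClassifier(
        hidden_layer_sizes=(10,),
        activation="relu",
        solver="sgd",
        alpha=0.0,
        batch_size=min(batch, xs.shape[0]),
        learning_rate_init=cfg.mlp_lr,
        momentum=0.0,
        nesterovs_momentum=False,
        max_iter=cfg.mlp_epochs,
        shuffle=True,
        random_state=cfg.seed,
        tol=cfg.tolerance,
        n_iter_no_change=cfg.mlp_epochs,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs, y)
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            "MLP training diverged (non-finite loss): try a smaller learning rate"
        )
    w1_s, w2 = net.coefs_  # (n_features x 10), (10 x 1)
    b1_s, b2 = net.intercepts_
    # fold the z-scoring into the first affine layer
    w1 = w1_s / sd[:, None]
    b1 = b1_s - (w1_s * (mu / sd)[:, None]).sum(axis=0)
    return MLPModel(
        hidden_weights=w1,
        hidden_bias=b1,
        output_weights=w2[:, 0],
        output_bias=float(b2[0]),
        seed=cfg.seed,
        positive_label=pos,
        negative_label=neg,
        loss_curve=np.asarray(net.loss_curve_),
    )


def decision_values(model: LinearModel | MLPModel, feats: FeatureMatrix) -> np.ndarray:
    """Signed decision value per trial (linear margin, or MLP probability - 0.5)."""
    x = feats.values
    if isinstance(model, LinearModel):
        if x.shape[1] != model.weights.size:
            raise ValueError(
                f"feature dimension {x.shape[1]} != model dimension "
                f"{model.weights.size}"
            )
        return x @ model.weights + model.bias
    if x.shape[1] != model.hidden_weights.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model dimension "
            f"{model.hidden_weights.shape[0]}"
        )
    h = np.maximum(0.0, x @ model.hidden_weights + model.hidden_bias)
    z = h @ model.output_weights + model.output_bias
    p = 1.0 / (1.0 + np.exp(-z))
    return p - 0.5


def predict(model: LinearModel | MLPModel, feats: FeatureMatrix) -> np.ndarray:
    """One label per trial; a trial exactly on the boundary goes positive."""
    d = decision_values(model, feats)
    return np.where(d >= 0.0, model.positive_label, model.negative_label)
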