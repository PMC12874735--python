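"""Multi-label classifiers: back-propagation MLP and one-vs-rest baselines.

Every model maps a gene's feature vector to one independent membership
probability per pathway. The multi-layer perceptron — feed-forward, ReLU
hidden layers, per-label sigmoid outputs — is trained by minimizing a
class-weighted binary cross-entropy summed over labels via back-propagation
(full-batch Adam, early stopping on an internal validation split). The
positive term of label j's loss is scaled by w_j = (#negatives_j /
#positives_j) to counter the dominance of large pathways.

The baselines (one-vs-rest SVM, random forest, gradient-boosted trees) train
one independent binary model per pathway on top of the established library
estimators; the SVM's probabilities come from a logistic map of its decision
values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

MODEL_KINDS = ("mlp", "svm_ovr", "random_forest", "gbt")


@dataclass
class LabelMatrix:
    """Binary gene × pathway membership matrix with its indices."""

    values: np.ndarray
    gene_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("label matrix shape does not match indices")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ScoreMatrix:
    """Predicted gene × pathway membership probabilities in [0, 1]."""

    values: np.ndarray
    gene_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("score matrix shape does not match indices")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ModelConfig:
    """Configuration shared by all model kinds; the seed is mandatory."""

    model_kind: str = "mlp"
    hidden_layers: list[int] = field(default_factory=lambda: [128])
    max_epochs: int = 1000
    learning_rate: float = 3e-3
    l2: float = 1e-4
    #: None = family default: the MLP loss is class-weighted, the library
    #: baselines keep their standard unweighted settings.
    class_weighting: bool | None = None
    seed: int = 0

    @property
    def effective_class_weighting(self) -> bool:
        if self.class_weighting is None:
            return self.model_kind == "mlp"
        return self.class_weighting

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {self.model_kind!r}")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_class_weights(labels: LabelMatrix | np.ndarray) -> np.ndarray:
    """Per-pathway positive-class weight: #negatives / #positives.

    A pathway with zero positives gets weight 1 with a warning (nothing to
    upweight).
    """
    Y = labels.values if isinstance(labels, LabelMatrix) else np.asarray(labels)
    n = Y.shape[0]
    pos = Y.sum(axis=0).astype(float)
    weights = np.ones_like(pos)
    nonzero = pos > 0
    weights[nonzero] = (n - pos[nonzero]) / pos[nonzero]
    if not nonzero.all():
        warnings.warn("pathway(s) with zero positive genes get weight 1",
                      stacklevel=2)
    return weights


# ---------------------------------------------------------------------------
# Multi-label MLP (back-propagation, numpy)


class MultiLabelMLP(BaseEstimator):
    """Feed-forward network with independent sigmoid outputs per pathway.

    Trained full-batch with Adam on the class-weighted multi-label binary
    cross-entropy; reproducible bit-for-bit under a fixed ``random_state``.
    Early stopping monitors the loss on an internal validation split (10% by
    default) and restores the best weights.
    """

    def __init__(self, hidden_layers: Sequence[int] = (128,),
                 max_epochs: int = 1000, learning_rate: float = 3e-3,
                 l2: float = 1e-4, class_weighting: bool = True,
                 validation_fraction: float = 0.1, patience: int = 50,
                 tol: float = 1e-5, threshold: float = 0.5,
                 random_state: int = 0):
        self.hidden_layers = hidden_layers
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.l2 = l2
        self.class_weighting = class_weighting
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.tol = tol
        self.threshold = threshold
        self.random_state = random_state

    # -- network plumbing ---------------------------------------------------

    def _init_weights(self, n_features: int, n_labels: int,
                      rng: np.random.Generator | None = None) -> None:
        """He-initialized weights (or zeros when rng is None)."""
        sizes = [n_features, *self.hidden_layers, n_labels]
        self.weights_ = []
        self.biases_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            if rng is None:
                W = np.zeros((fan_in, fan_out))
            else:
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights_.append(W)
            self.biases_.append(np.zeros(fan_out))
        self.n_features_in_ = n_features
        self.n_labels_ = n_labels

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        activations = [X]
        h = X
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            activations.append(h)
        logits = h @ self.weights_[-1] + self.biases_[-1]
        return activations, logits

    def _loss_and_grads(self, X, Y, w):
        n = X.shape[0]
        activations, logits = self._forward(X)
        P = expit(logits)
        Pc = np.clip(P, 1e-12, 1 - 1e-12)
        loss = float(np.mean(
            np.sum(-w * Y * np.log(Pc) - (1 - Y) * np.log(1 - Pc), axis=1)))
        loss += 0.5 * self.l2 * sum(float(np.sum(W * W)) for W in self.weights_)

        # dL/dlogit for the weighted BCE: (1−y)·p − w·y·(1−p), averaged over n.
        delta = ((1 - Y) * P - w * Y * (1 - P)) / n
        grads_W, grads_b = [], []
        for layer in range(len(self.weights_) - 1, -1, -1):
            a = activations[layer]
            grads_W.append(a.T @ delta + self.l2 * self.weights_[layer])
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights_[layer].T) * (activations[layer] > 0)
        return loss, grads_W[::-1], grads_b[::-1]

    def _val_loss(self, X, Y, w) -> float:
        _, logits = self._forward(X)
        Pc = np.clip(expit(logits), 1e-12, 1 - 1e-12)
        return float(np.mean(
            np.sum(-w * Y * np.log(Pc) - (1 - Y) * np.log(1 - Pc), axis=1)))

    # -- estimator API ------------------------------------------------------

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y)
        Y = Y.astype(float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("feature and label row counts differ")
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        K = Y.shape[1]
        w = compute_class_weights(Y) if self.class_weighting else np.ones(K)

        # Internal validation split for early stopping.
        n_val = int(round(self.validation_fraction * n))
        if n_val >= 2 and n - n_val >= 2:
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx = tr_idx = np.arange(n)
        Xtr, Ytr = X[tr_idx], Y[tr_idx]
        Xval, Yval = X[val_idx], Y[val_idx]

        self._init_weights(d, K, rng)
        params = self.weights_ + self.biases_
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best = [p.copy() for p in params]
        stale = 0
        self.loss_curve_ = []
        for epoch in range(1, self.max_epochs + 1):
            loss, gW, gb = self._loss_and_grads(Xtr, Ytr, w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            self.loss_curve_.append(loss)
            grads = gW + gb
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mhat = m[i] / (1 - b1 ** epoch)
                vhat = v[i] / (1 - b2 ** epoch)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val = self._val_loss(Xval, Yval, w)
            if val < best_val - self.tol:
                best_val = val
                best = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        k = len(self.weights_)
        self.weights_ = best[:k]
        self.biases_ = best[k:]
        self.class_weights_ = w
        self.n_epochs_ = epoch
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} does not match training width "
                f"{self.n_features_in_}")
        _, logits = self._forward(X)
        return expit(logits)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# One-vs-rest baselines


class _ConstantBinary:
    """Fallback when a training fold contains a single class for a label."""

    def __init__(self, p: float):
        self.p = p

    def proba(self, X) -> np.ndarray:
        return np.full(X.shape[0], self.p)


class MultiLabelOvR(BaseEstimator):
    """One independent binary classifier per pathway.

    ``kind`` selects the base family: ``svm_ovr`` (RBF SVM; probabilities are
    the logistic map of the decision values), ``random_forest``, or ``gbt``
    (XGBoost). Degenerate single-class labels in the training data fall back
    to a constant predictor at that class's value.
    """

    def __init__(self, kind: str = "svm_ovr", class_weighting: bool = False,
                 threshold: float = 0.5, random_state: int = 0,
                 n_estimators: int = 100):
        self.kind = kind
        self.class_weighting = class_weighting
        self.threshold = threshold
        self.random_state = random_state
        self.n_estimators = n_estimators

    def _make_binary(self, pos_frac: float):
        if self.kind == "svm_ovr":
            return SVC(kernel="rbf", gamma="scale",
                       class_weight="balanced" if self.class_weighting else None,
                       random_state=self.random_state)
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                class_weight="balanced" if self.class_weighting else None,
                random_state=self.random_state, n_jobs=1)
        if self.kind == "gbt":
            from xgboost import XGBClassifier

            spw = ((1 - pos_frac) / pos_frac
                   if self.class_weighting and 0 < pos_frac < 1 else 1.0)
            return XGBClassifier(
                n_estimators=self.n_estimators, max_depth=4,
                learning_rate=0.1, scale_pos_weight=spw, verbosity=0,
                random_state=self.random_state, n_jobs=1,
                eval_metric="logloss")
        raise ValueError(f"unknown baseline kind: {self.kind!r}")

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y)
        self.n_features_in_ = X.shape[1]
        self.n_labels_ = Y.shape[1]
        self.estimators_ = []
        for j in range(Y.shape[1]):
            y = Y[:, j].astype(int)
            if y.min() == y.max():
                self.estimators_.append(_ConstantBinary(float(y[0])))
                continue
            est = self._make_binary(float(y.mean()))
            est.fit(X, y)
            self.estimators_.append(est)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} does not match training width "
                f"{self.n_features_in_}")
        cols = []
        for est in self.estimators_:
            if isinstance(est, _ConstantBinary):
                cols.append(est.proba(X))
            elif isinstance(est, SVC):
                cols.append(expit(est.decision_function(X)))
            else:
                cols.append(est.predict_proba(X)[:, 1])
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# Factory and thin wrappers


def make_model(config: ModelConfig):
    """Instantiate the estimator described by a :class:`ModelConfig`."""
    if config.model_kind == "mlp":
        return MultiLabelMLP(hidden_layers=list(config.hidden_layers),
                             max_epochs=config.max_epochs,
                             learning_rate=config.learning_rate, l2=config.l2,
                             class_weighting=config.effective_class_weighting,
                             random_state=config.seed)
    return MultiLabelOvR(kind=config.model_kind,
                         class_weighting=config.effective_class_weighting,
                         random_state=config.seed)


def train_mlp(features, labels: LabelMatrix, config: ModelConfig) -> MultiLabelMLP:
    model = MultiLabelMLP(hidden_layers=list(config.hidden_layers),
                          max_epochs=config.max_epochs,
                          learning_rate=config.learning_rate, l2=config.l2,
                          class_weighting=config.effective_class_weighting,
                          random_state=config.seed)
    return model.fit(features, labels)


def train_baseline(kind: str, features, labels: LabelMatrix,
                   config: ModelConfig) -> MultiLabelOvR:
    model = MultiLabelOvR(kind=kind,
                          class_weighting=config.effective_class_weighting,
                          random_state=config.seed)
    return model.fit(features, labels)


def predict_proba(model, features, gene_ids: list[str] | None = None,
                  pathway_ids: list[str] | None = None):
    """Predicted probabilities; a ScoreMatrix when both indices are given."""
    P = model.predict_proba(np.asarray(features, dtype=float))
    if gene_ids is not None and pathway_ids is not None:
        return ScoreMatrix(values=P, gene_ids=gene_ids, pathway_ids=pathway_ids)
    return P
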