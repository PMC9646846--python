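"""Classifiers: the DE+MLP teacher, linear baselines, and a shared logits
contract.

The multilayer perceptron (one hidden layer of 248 rectified units, dropout
0.5, trained by Adam on cross-entropy) is implemented in numpy.  The same
trainer accepts soft target distributions mixed with hard labels through an
imitation factor, which is what privileged-information distillation needs;
with ``hidden_size=None`` it degenerates to a multinomial linear model and
serves as the video-only student.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

__all__ = [
    "softmax",
    "ClassifierSpec",
    "LogitsRecord",
    "NeuralClassifier",
    "SVMClassifier",
    "train_classifier",
]


def softmax(logits: np.ndarray, temperature: float = 1.0, axis: int = -1) -> np.ndarray:
    """Temperature softmax ``exp(z_k / T) / sum_j exp(z_j / T)``.

    Numerically stable (max-shifted); invariant to adding a constant to all
    logits.  ``temperature`` must be positive: large values flatten the
    distribution towards uniform, small ones sharpen it towards the argmax.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    z = np.asarray(logits, dtype=float) / temperature
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ClassifierSpec:
    kind: str = "de_mlp"  # de_mlp | linear_svm | linear_student
    n_classes: int = 10
    hidden_size: int = 248
    dropout_rate: float = 0.5
    seed: int = 0
    learning_rate: float = 5e-3
    max_epochs: int = 200
    patience: int = 25

    def __post_init__(self) -> None:
        if self.kind not in ("de_mlp", "linear_svm", "linear_student"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class LogitsRecord:
    """Un-normalised class scores of one model for one stimulus instance."""

    logits: np.ndarray
    model_id: str
    subject_id: int
    stimulus_id: int


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"feature/label mismatch: {X.shape[0]} vs {y.shape[0]} rows")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")


class NeuralClassifier:
    """One-hidden-layer ReLU network (or linear model) trained with Adam.

    The loss is a convex combination of hard-label cross-entropy and
    soft-target cross-entropy weighted by ``imitation`` (0 = hard labels
    only).  Dropout is applied to the hidden layer during training only;
    inference is deterministic.  Identical spec + seed + data reproduce
    identical parameters.
    """

    def __init__(self, n_classes: int, hidden_size: int | None = 248,
                 dropout_rate: float = 0.5, seed: int = 0,
                 learning_rate: float = 5e-3, max_epochs: int = 200,
                 patience: int = 25, weight_decay: float = 0.0):
        self.n_classes = n_classes
        self.hidden_size = hidden_size
        self.dropout_rate = dropout_rate if hidden_size else 0.0
        self.seed = seed
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.params_: dict[str, np.ndarray] | None = None

    # -- forward / backward -------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> dict:
        if self.hidden_size:
            return {
                "W1": rng.standard_normal((n_features, self.hidden_size))
                * np.sqrt(2.0 / n_features),
                "b1": np.zeros(self.hidden_size),
                "W2": rng.standard_normal((self.hidden_size, self.n_classes))
                * np.sqrt(2.0 / self.hidden_size),
                "b2": np.zeros(self.n_classes),
            }
        return {
            "W2": rng.standard_normal((n_features, self.n_classes))
            * np.sqrt(1.0 / n_features),
            "b2": np.zeros(self.n_classes),
        }

    def _forward(self, X: np.ndarray, params: dict, drop_mask: np.ndarray | None = None):
        if self.hidden_size:
            h = np.maximum(X @ params["W1"] + params["b1"], 0.0)
            if drop_mask is not None:
                h = h * drop_mask
            return h @ params["W2"] + params["b2"], h
        return X @ params["W2"] + params["b2"], None

    def _grads(self, X, h, dlogits, params, drop_mask):
        g = {"W2": (h if self.hidden_size else X).T @ dlogits,
             "b2": dlogits.sum(axis=0)}
        if self.hidden_size:
            dh = dlogits @ params["W2"].T
            if drop_mask is not None:
                dh = dh * drop_mask
            dh[h <= 0] = 0.0
            g["W1"] = X.T @ dh
            g["b1"] = dh.sum(axis=0)
        return g

    # -- training -----------------------------------------------------------

    def fit(self, X, y, soft_targets=None, imitation: float = 0.0,
            X_val=None, y_val=None) -> "NeuralClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_training_inputs(X, y)
        if not 0 <= imitation <= 1:
            raise ValueError(f"imitation factor must lie in [0, 1], got {imitation}")
        if soft_targets is not None:
            soft_targets = np.asarray(soft_targets, dtype=float)
            if soft_targets.shape != (X.shape[0], self.n_classes):
                raise ValueError(
                    f"soft targets misaligned: {soft_targets.shape} vs "
                    f"({X.shape[0]}, {self.n_classes})"
                )
        elif imitation > 0:
            raise ValueError("imitation > 0 requires soft targets")

        rng = np.random.default_rng(self.seed)
        params = self._init_params(X.shape[1], rng)
        onehot = np.eye(self.n_classes)[y]
        n = X.shape[0]
        # Adam state
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val, best_params, stall = -np.inf, None, 0

        for epoch in range(1, self.max_epochs + 1):
            if self.dropout_rate > 0:
                drop_mask = (
                    rng.random((n, self.hidden_size)) >= self.dropout_rate
                ) / (1.0 - self.dropout_rate)
            else:
                drop_mask = None
            logits, h = self._forward(X, params, drop_mask)
            p = softmax(logits)
            # d(loss)/d(logits) of the convex-combination cross-entropy
            dlogits = ((1.0 - imitation) * (p - onehot)) / n
            if imitation > 0:
                dlogits = dlogits + imitation * (p - soft_targets) / n
            grads = self._grads(X, h, dlogits, params, drop_mask)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**epoch)
                vhat = v[k] / (1 - beta2**epoch)
                step = self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                if self.weight_decay and k.startswith("W"):
                    step = step + self.learning_rate * self.weight_decay * params[k]
                params[k] = params[k] - step

            if X_val is not None and epoch % 5 == 0:
                self.params_ = params
                acc = float(np.mean(self.predict(X_val) == y_val))
                if acc > best_val:
                    best_val, stall = acc, 0
                    best_params = {k: p_.copy() for k, p_ in params.items()}
                else:
                    stall += 5
                    if stall >= self.patience:
                        break

        self.params_ = best_params if best_params is not None else params
        return self

    # -- inference ----------------------------------------------------------

    def predict_logits(self, X) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        logits, _ = self._forward(X, self.params_)
        return logits

    def predict_proba(self, X, temperature: float = 1.0) -> np.ndarray:
        return softmax(self.predict_logits(X), temperature)

    def predict(self, X) -> np.ndarray:
        # argmax with lowest-index tie-break (numpy argmax contract)
        return np.argmax(self.predict_logits(X), axis=-1)


class SVMClassifier:
    """Linear SVM baseline (default regularisation C = 1) exposing the same
    logits/predict contract; one-vs-rest decision scores play the logit role."""

    def __init__(self, n_classes: int, seed: int = 0, C: float = 1.0):
        self.n_classes = n_classes
        self._svm = LinearSVC(C=C, random_state=seed, max_iter=10000)

    def fit(self, X, y, **_ignored) -> "SVMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_training_inputs(X, y)
        self._svm.fit(X, y)
        return self

    def predict_logits(self, X) -> np.ndarray:
        scores = self._svm.decision_function(np.asarray(X, dtype=float))
        if scores.ndim == 1:  # binary: expand to per-class scores
            scores = np.column_stack([-scores, scores])
        full = np.full((scores.shape[0], self.n_classes), -np.inf)
        full[:, self._svm.classes_] = scores
        # absent classes get a score below every present one
        finite_min = scores.min() - 1.0
        full[np.isinf(full)] = finite_min
        return full

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_logits(X), axis=-1)


def train_classifier(spec: ClassifierSpec, X, y, X_val=None, y_val=None):
    """Train the classifier named by ``spec.kind`` and return a model with
    ``predict_logits`` / ``predict``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_training_inputs(X, y)
    if spec.kind == "linear_svm":
        return SVMClassifier(spec.n_classes, seed=spec.seed).fit(X, y)
    hidden = spec.hidden_size if spec.kind == "de_mlp" else None
    model = NeuralClassifier(
        n_classes=spec.n_classes,
        hidden_size=hidden,
        dropout_rate=spec.dropout_rate,
        seed=spec.seed,
        learning_rate=spec.learning_rate,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
    )
    return model.fit(X, y, X_val=X_val, y_val=y_val)
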