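"""The masked two-layer predictive model over a gene→complex factor graph.

The first layer computes one "complex activity" unit per complex: a weighted
sum over the member genes only, enforced by multiplying both the weights and
their gradients by the factor-graph membership mask, followed by a
configurable nonlinearity (ReLU by default). The second layer maps complex
activities to class logits with complete connections. Training minimizes
multinomial cross-entropy with minibatch Adam, Xavier-uniform initialization
and early stopping on a stratified validation split.

Everything is implemented in numpy and presented as a scikit-learn
estimator (:class:`FactorGraphClassifier`), so it composes with sklearn
model selection. All randomness flows from ``random_state`` through
``numpy.random.SeedSequence(random_state).spawn(3)`` — one child stream each
for weight initialization, the validation split and minibatch shuffling —
so any stage is independently reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit

from .factor import FactorGraph
from .io import ExpressionDataset

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FactorGraphClassifier",
    "build_model",
    "forward",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("relu", "identity", "tanh")


@dataclass
class ModelSpec:
    factor_graph: FactorGraph
    n_classes: int
    activation: str = "relu"
    use_bias: bool = True

    def validate(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    validation_fraction: float = 0.25
    patience: int = 20
    seed: int = 0

    def validate(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.max_epochs < 0 or self.patience < 1:
            raise ValueError("max_epochs must be >= 0 and patience >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def _activation(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    return z


def _activation_grad(name: str, z: np.ndarray, h: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "tanh":
        return 1.0 - h * h
    return np.ones_like(z)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    """Plain Adam; one instance per parameter tensor."""

    def __init__(self, shape, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return param - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class FactorGraphClassifier(ClassifierMixin, BaseEstimator):
    """Masked gene→complex→phenotype classifier.

    Parameters
    ----------
    factor_graph : FactorGraph
        Bipartite membership structure; its mask constrains the first layer.
    activation : {"relu", "identity", "tanh"}
        Nonlinearity of the complex-activity units.
    use_bias : bool
        Whether both layers carry bias terms (biases are excluded from the
        factor-graph parameter accounting either way).
    learning_rate, batch_size, max_epochs, validation_fraction, patience
        Training protocol; defaults are Adam at 1e-4, minibatches of 32,
        500 epochs, a stratified quarter of the training data held out for
        early stopping with patience 20 and best-weights restore.
    xavier_fan : {"dense", "per_complex"}
        Whether the first-layer Xavier-uniform range uses the dense (k, l)
        fan (default) or each complex's own fan-in.
    random_state : int or None
        Master seed for initialization, the validation split and shuffling.

    Attributes
    ----------
    classes_ : ndarray — class vocabulary, sorted.
    W1_, b1_, W2_, b2_ : weights; ``W1_`` is exactly zero off the mask.
    mask_ : boolean (k, l) membership mask.
    history_ : dict with per-epoch "train_loss" and "val_loss" lists.
    best_epoch_ : epoch whose weights were restored.
    """

    def __init__(self, factor_graph=None, activation="relu", use_bias=True,
                 learning_rate=1e-4, batch_size=32, max_epochs=500,
                 validation_fraction=0.25, patience=20, xavier_fan="dense",
                 random_state=None):
        self.factor_graph = factor_graph
        self.activation = activation
        self.use_bias = use_bias
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.xavier_fan = xavier_fan
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _seed_streams(self):
        ss = np.random.SeedSequence(self.random_state)
        return ss.spawn(3)  # init, split, shuffle

    def initialize(self, classes):
        """Set Xavier-uniform initial weights (masked) without training."""
        if self.factor_graph is None:
            raise ValueError("factor_graph is required")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        classes = np.asarray(sorted(set(np.asarray(classes).tolist())),
                             dtype=object)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        self.classes_ = classes
        k, l, c = (self.factor_graph.n_genes, self.factor_graph.n_complexes,
                   classes.size)
        self.mask_ = self.factor_graph.mask()
        init_ss, _, _ = self._seed_streams()
        rng = np.random.default_rng(init_ss)
        limit1 = np.sqrt(6.0 / (k + l))
        w1 = rng.uniform(-limit1, limit1, size=(k, l))
        if self.xavier_fan == "per_complex":
            fan_in = np.maximum(self.mask_.sum(axis=0), 1)
            w1 = w1 / limit1 * np.sqrt(6.0 / (fan_in + 1))[None, :]
        elif self.xavier_fan != "dense":
            raise ValueError("xavier_fan must be 'dense' or 'per_complex'")
        self.W1_ = np.where(self.mask_, w1, 0.0)
        limit2 = np.sqrt(6.0 / (l + c))
        self.W2_ = rng.uniform(-limit2, limit2, size=(l, c))
        self.b1_ = np.zeros(l)
        self.b2_ = np.zeros(c)
        self.history_ = {"train_loss": [], "val_loss": []}
        self.best_epoch_ = 0
        self.n_features_in_ = k
        return self

    # -- forward pass ------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.factor_graph.n_genes:
            raise ValueError(
                f"X must have {self.factor_graph.n_genes} columns in the "
                "factor graph's gene order"
            )
        return X

    def _forward(self, X):
        z = X @ self.W1_ + self.b1_
        h = _activation(self.activation, z)
        logits = h @ self.W2_ + self.b2_
        return z, h, logits

    def complex_activities(self, X) -> np.ndarray:
        """The m × l matrix of complex activities f_ci(x)."""
        _, h, _ = self._forward(self._check_X(X))
        return h

    def decision_function(self, X) -> np.ndarray:
        _, _, logits = self._forward(self._check_X(X))
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    # -- training ----------------------------------------------------------

    def _loss(self, X, y_idx) -> float:
        p = _softmax(self._forward(X)[2])
        eps = 1e-12
        return float(-np.mean(np.log(p[np.arange(len(y_idx)), y_idx] + eps)))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.initialize(np.unique(y))
        X = self._check_X(X)
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.asarray([class_pos[v] for v in y])

        if self.max_epochs == 0:
            return self

        _, split_ss, shuffle_ss = self._seed_streams()
        if self.validation_fraction > 0.0:
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=self.validation_fraction,
                random_state=int(split_ss.generate_state(1)[0] % (2 ** 31)),
            )
            try:
                tr, va = next(splitter.split(X, y_idx))
            except ValueError as exc:
                raise ValueError(
                    "stratified validation split failed (a class may have "
                    f"too few samples): {exc}"
                ) from exc
            if len(set(y_idx[tr])) < self.classes_.size:
                raise ValueError("a class is absent from the training portion")
        else:
            tr, va = np.arange(len(y_idx)), None
        X_tr, y_tr = X[tr], y_idx[tr]

        lr = self.learning_rate
        opt = {name: _Adam(getattr(self, name).shape, lr)
               for name in ("W1_", "b1_", "W2_", "b2_")}
        rng = np.random.default_rng(shuffle_ss)
        n = len(y_tr)
        best_loss, best_weights, best_epoch = np.inf, None, 0
        eye = np.eye(self.classes_.size)

        for epoch in range(1, self.max_epochs + 1):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                xb, yb = X_tr[idx], y_tr[idx]
                z, h, logits = self._forward(xb)
                p = _softmax(logits)
                dlogits = (p - eye[yb]) / len(idx)
                dW2 = h.T @ dlogits
                db2 = dlogits.sum(axis=0)
                dh = dlogits @ self.W2_.T
                dz = dh * _activation_grad(self.activation, z, h)
                dW1 = (xb.T @ dz) * self.mask_
                db1 = dz.sum(axis=0)
                self.W1_ = opt["W1_"].step(self.W1_, dW1) * self.mask_
                self.W2_ = opt["W2_"].step(self.W2_, dW2)
                if self.use_bias:
                    self.b1_ = opt["b1_"].step(self.b1_, db1)
                    self.b2_ = opt["b2_"].step(self.b2_, db2)

            train_loss = self._loss(X_tr, y_tr)
            self.history_["train_loss"].append(train_loss)
            if va is not None:
                monitor = self._loss(X[va], y_idx[va])
                self.history_["val_loss"].append(monitor)
            else:
                monitor = train_loss
            if not np.isfinite(monitor):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}"
                )
            if monitor < best_loss:
                best_loss = monitor
                best_epoch = epoch
                best_weights = {name: getattr(self, name).copy()
                                for name in ("W1_", "b1_", "W2_", "b2_")}
            elif epoch - best_epoch >= self.patience:
                break

        if best_weights is not None:
            for name, value in best_weights.items():
                setattr(self, name, value)
        self.best_epoch_ = best_epoch
        return self

    def n_trainable_edges(self) -> int:
        """Number of first-layer weights the mask allows (= factor-graph
        edge count)."""
        return int(self.mask_.sum())


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, seed=None) -> FactorGraphClassifier:
    """Untrained model with Xavier-uniform masked initial weights."""
    spec.validate()
    clf = FactorGraphClassifier(
        factor_graph=spec.factor_graph, activation=spec.activation,
        use_bias=spec.use_bias, random_state=seed,
    )
    return clf.initialize(list(range(spec.n_classes)))


def forward(model: FactorGraphClassifier, X):
    """(complex activities m × l, class logits m × n_classes)."""
    X = model._check_X(X)
    _, h, logits = model._forward(X)
    return h, logits


def train(model: FactorGraphClassifier, dataset: ExpressionDataset,
          cfg: TrainConfig) -> FactorGraphClassifier:
    """Fit ``model`` on a labelled expression dataset per the train config."""
    cfg.validate()
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    model.set_params(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        validation_fraction=cfg.validation_fraction,
        patience=cfg.patience, random_state=cfg.seed,
    )
    return model.fit(dataset.values, dataset.labels)


def predict_proba(model: FactorGraphClassifier, X) -> np.ndarray:
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: FactorGraphClassifier, path) -> None:
    """Save weights, mask, factor graph and history to an .npz checkpoint."""
    fg = model.factor_graph
    genes = np.asarray(fg.gene_index, dtype=str)
    complexes = np.asarray(fg.complex_names, dtype=str)
    pairs = sorted(fg.memberships)
    np.savez(
        path,
        W1=model.W1_, b1=model.b1_, W2=model.W2_, b2=model.b2_,
        classes=np.asarray(model.classes_, dtype=str),
        genes=genes, complexes=complexes,
        member_genes=np.asarray([g for g, _ in pairs], dtype=str),
        member_complexes=np.asarray([c for _, c in pairs], dtype=str),
        origin=np.asarray([fg.origin], dtype=str),
        activation=np.asarray([model.activation], dtype=str),
        use_bias=np.asarray([model.use_bias]),
        best_epoch=np.asarray([model.best_epoch_]),
        train_loss=np.asarray(model.history_["train_loss"]),
        val_loss=np.asarray(model.history_["val_loss"]),
    )


def load_model(path) -> FactorGraphClassifier:
    data = np.load(path, allow_pickle=False)
    fg = FactorGraph(
        gene_index=list(data["genes"]),
        complex_names=list(data["complexes"]),
        memberships=set(zip(data["member_genes"].tolist(),
                            data["member_complexes"].tolist())),
        origin=str(data["origin"][0]),
    )
    clf = FactorGraphClassifier(
        factor_graph=fg, activation=str(data["activation"][0]),
        use_bias=bool(data["use_bias"][0]),
    )
    clf.classes_ = np.asarray(data["classes"].tolist(), dtype=object)
    clf.mask_ = fg.mask()
    clf.W1_, clf.b1_ = data["W1"], data["b1"]
    clf.W2_, clf.b2_ = data["W2"], data["b2"]
    clf.best_epoch_ = int(data["best_epoch"][0])
    clf.history_ = {"train_loss": data["train_loss"].tolist(),
                    "val_loss": data["val_loss"].tolist()}
    clf.n_features_in_ = fg.n_genes
    return clf
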