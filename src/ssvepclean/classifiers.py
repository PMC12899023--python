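"""Trainable SSVEP classifiers on harmonic FFT features.

Two models operate on the same 27-dimensional feature space:

* a multi-class linear-kernel SVM (one-vs-rest, C = 1, hinge loss,
  features standardized by training statistics), and
* "compact_net", a small dense network — per-feature z-score input
  normalization, one 64-unit rectified hidden layer, dropout 0.5 and a
  softmax output — trained with Adam (batch 64, up to 40 epochs) and
  early stopping (patience 3) on a class-balanced validation split of
  ~12.5% of the training data.

The network is trained ``n_runs`` (default 3) times with distinct seeds
to average out initialization effects; prediction keeps the runs
separate so accuracy can be reported as mean ± SD across runs, without
ensembling.  Both models are deterministic given data and seeds, and
neither mutates its input features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .spectral_features import FeatureMatrix

__all__ = [
    "NetConfig",
    "TrainedModel",
    "train_linear_svm",
    "train_compact_net",
    "predict",
]


@dataclass
class NetConfig:
    hidden_units: int = 64
    dropout: float = 0.5
    max_epochs: int = 40
    batch_size: int = 64
    val_fraction: float = 0.125  # class-balanced, floor with >= 1 per class
    patience: int = 3
    n_runs: int = 3
    learning_rate: float = 1e-3  # Adam
    seed_base: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        for name in ("hidden_units", "max_epochs", "batch_size", "patience", "n_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier; ``parameters`` are kind-specific weights."""

    kind: str  # "linear_svm" | "compact_net"
    classes: np.ndarray  # ordered stimulus frequencies
    normalization: tuple[np.ndarray, np.ndarray]  # training-set (mean, sd)
    parameters: object
    run_seeds: list[int] = field(default_factory=list)


def _check_features(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels, dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    if np.isnan(y).any():
        raise ValueError("training labels contain unlabelled epochs")
    return X, y


def train_linear_svm(features: FeatureMatrix, C: float = 1.0) -> TrainedModel:
    """Fit the one-vs-rest linear SVM on standardized features."""
    X, y = _check_features(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes to train")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=C, loss="hinge", max_iter=50000, random_state=0)),
        ]
    )
    pipe.fit(X, y)
    scaler: StandardScaler = pipe.named_steps["scale"]
    return TrainedModel(
        kind="linear_svm",
        classes=classes,
        normalization=(scaler.mean_.copy(), scaler.scale_.copy()),
        parameters=pipe,
    )


# ---------------------------------------------------------------------------
# compact_net (plain-numpy dense network)


def _balanced_val_split(
    y: np.ndarray, classes: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of validation rows: per class floor(frac*n_c), >= 1."""
    mask = np.zeros(y.size, dtype=bool)
    for c in classes:
        idx = np.flatnonzero(y == c)
        n_val = max(1, int(np.floor(frac * idx.size)))
        if n_val >= idx.size:
            raise ValueError(f"class {c} too small for a validation split")
        mask[rng.permutation(idx)[:n_val]] = True
    return mask


class _DenseNet:
    """dense(hidden)+ReLU -> dropout -> dense(n_classes)+softmax, Adam-trained."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / n_hidden), (n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def logits(self, Z: np.ndarray) -> np.ndarray:
        return np.maximum(Z @ self.W1 + self.b1, 0.0) @ self.W2 + self.b2

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, Z: np.ndarray, onehot: np.ndarray) -> float:
        p = self._softmax(self.logits(Z))
        return float(-np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1)))

    def grads(
        self, Z: np.ndarray, onehot: np.ndarray, dropout: float, rng: np.random.Generator
    ):
        h_pre = Z @ self.W1 + self.b1
        h = np.maximum(h_pre, 0.0)
        if dropout > 0:
            keep = rng.random(h.shape) >= dropout
            h = h * keep / (1.0 - dropout)  # inverted dropout
        p = self._softmax(h @ self.W2 + self.b2)
        n = Z.shape[0]
        dlogits = (p - onehot) / n
        gW2 = h.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        if dropout > 0:
            dh = dh * keep / (1.0 - dropout)
        dh_pre = dh * (h_pre > 0)
        gW1 = Z.T @ dh_pre
        gb1 = dh_pre.sum(axis=0)
        return [gW1, gb1, gW2, gb2]


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_one_run(
    Z: np.ndarray, y_idx: np.ndarray, n_classes: int, cfg: NetConfig, seed: int
) -> tuple[_DenseNet, int]:
    """One seeded training run; returns the best-validation-loss network."""
    rng = np.random.default_rng(seed)
    classes = np.arange(n_classes)
    val_mask = _balanced_val_split(y_idx, classes, cfg.val_fraction, rng)
    Ztr, ytr = Z[~val_mask], y_idx[~val_mask]
    Zval, yval = Z[val_mask], y_idx[val_mask]
    onehot_tr = np.eye(n_classes)[ytr]
    onehot_val = np.eye(n_classes)[yval]

    net = _DenseNet(Z.shape[1], cfg.hidden_units, n_classes, rng)
    opt = _Adam(net.params(), cfg.learning_rate)
    best_loss = np.inf
    best_state = [p.copy() for p in net.params()]
    bad_epochs = 0
    epochs_run = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(Ztr.shape[0])
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grads = net.grads(Ztr[batch], onehot_tr[batch], cfg.dropout, rng)
            opt.step(net.params(), grads)
        epochs_run += 1
        val_loss = net.loss(Zval, onehot_val)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_state = [p.copy() for p in net.params()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    for p, b in zip(net.params(), best_state):
        p[...] = b
    return net, epochs_run


def train_compact_net(
    features: FeatureMatrix, cfg: NetConfig | None = None
) -> TrainedModel:
    """Train the compact dense network ``cfg.n_runs`` times with distinct seeds."""
    cfg = cfg or NetConfig()
    X, y = _check_features(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes to train")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 1.0 / cfg.val_fraction * 2:
        raise ValueError("too few samples per class for a balanced validation split")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    y_idx = np.searchsorted(classes, y)
    seeds = [cfg.seed_base + i for i in range(cfg.n_runs)]
    runs = [_train_one_run(Z, y_idx, classes.size, cfg, s) for s in seeds]
    return TrainedModel(
        kind="compact_net",
        classes=classes,
        normalization=(mean, sd),
        parameters={"nets": [net for net, _ in runs],
                    "epochs_run": [e for _, e in runs],
                    "cfg": cfg},
        run_seeds=seeds,
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Predict stimulus frequencies.

    linear_svm -> (n_epochs,) labels; compact_net -> (n_runs, n_epochs)
    labels, one row per training run (accuracy is averaged downstream,
    never majority-voted).
    """
    X = np.asarray(features.values, dtype=float)
    if X.shape[1] != model.normalization[0].size:
        raise ValueError("feature dimensionality does not match training")
    if model.kind == "linear_svm":
        return model.parameters.predict(X)
    if model.kind == "compact_net":
        mean, sd = model.normalization
        Z = (X - mean) / sd
        out = []
        for net in model.parameters["nets"]:
            out.append(model.classes[np.argmax(net.logits(Z), axis=1)])
        return np.vstack(out)
    raise ValueError(f"unknown model kind {model.kind!r}")
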