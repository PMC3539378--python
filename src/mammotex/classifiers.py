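"""Binary classifiers operating on texture feature vectors.

Three classifiers are provided, all exposing the same minimal interface
(``fit(X, y)``, ``decision_scores(X)``, ``predict(X)``) with the positive
class (mass) encoded as 1:

* :class:`MLP` — a single-hidden-layer perceptron with sigmoid activations
  and one sigmoid output, trained by backpropagation on the mean squared
  error.  Defaults: 20 hidden units, at most 2000 iterations, stopping
  early when the training MSE drops below 0.001.  The continuous sigmoid
  output in (0, 1) is the ROC score.
* :class:`LinearSVM` — a support-vector machine whose decision function is
  ``C(x) = sum_i a_i <s_i, x> + b`` over the support vectors; ``C(x) >= 0``
  assigns the positive class.  Fitting is delegated to scikit-learn's SVC;
  the stored dual coefficients make the model JSON-serializable and the
  decision function explicit.
* :class:`KNN` — k-nearest neighbors under the Euclidean metric with
  majority vote; the score is the fraction of the k neighbors voting for
  the positive class.  Distance ties are broken by training-set order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "sigmoid",
    "relative_error",
    "mean_squared_error",
    "MLPConfig",
    "MLP",
    "LinearSVM",
    "KNN",
    "make_classifier",
    "model_from_dict",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic activation 1 / (1 + exp(-x)), numerically stable."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relative_error(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Signed mean residual sum(y - T) / n.

    This is the literal network relative error (positive and negative
    residuals cancel); use :func:`mean_squared_error` for the training
    stopping rule.
    """
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")
    if y.size == 0:
        raise ValueError("no samples")
    return float(np.sum(y - t) / y.size)


def mean_squared_error(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean of squared residuals; drives the MLP stopping rule."""
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.size == 0:
        raise ValueError("no samples")
    return float(np.mean((y - t) ** 2))


@dataclass
class MLPConfig:
    """Architecture and training hyperparameters of the perceptron.

    ``hidden_units``, ``max_iterations`` and ``target_mse`` are the
    standard operating point (20 / 2000 / 0.001); the optimizer settings
    are implementation choices documented in the methods note.
    """

    hidden_units: int = 20
    max_iterations: int = 2000
    target_mse: float = 1e-3
    learning_rate: float = 0.05
    init_scale: float = 0.5
    standardize: bool = True
    seed: int = 0


class MLP:
    """Single-hidden-layer sigmoid perceptron trained on MSE by Adam."""

    def __init__(self, config: MLPConfig | None = None, **kwargs) -> None:
        if config is None:
            config = MLPConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword overrides, not both")
        self.config = config
        self.w1: np.ndarray | None = None
        self.b1: np.ndarray | None = None
        self.w2: np.ndarray | None = None
        self.b2: float = 0.0
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self.n_iterations_: int = 0
        self.final_mse_: float = float("nan")

    # -- internals ---------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if not self.config.standardize:
            return X
        return (X - self._mu) / self._sd

    def _forward(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = sigmoid(Xs @ self.w1 + self.b1)
        y = sigmoid(h @ self.w2 + self.b2)
        return h, y

    # -- public API --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLP":
        X = np.asarray(X, dtype=np.float64)
        t = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("need a non-empty (n, d) feature matrix")
        if X.shape[0] != t.size:
            raise ValueError(f"{X.shape[0]} samples but {t.size} labels")
        if not np.isin(t, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        cfg = self.config
        if cfg.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        Xs = self._prepare(X)

        rng = np.random.default_rng(cfg.seed)
        d, h = X.shape[1], cfg.hidden_units
        self.w1 = rng.uniform(-cfg.init_scale, cfg.init_scale, size=(d, h))
        self.b1 = rng.uniform(-cfg.init_scale, cfg.init_scale, size=h)
        self.w2 = rng.uniform(-cfg.init_scale, cfg.init_scale, size=h)
        self.b2 = float(rng.uniform(-cfg.init_scale, cfg.init_scale))

        params = [self.w1, self.b1, self.w2]
        m = [np.zeros_like(p) for p in params] + [0.0]
        v = [np.zeros_like(p) for p in params] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]

        for it in range(1, cfg.max_iterations + 1):
            hid, out = self._forward(Xs)
            err = out - t
            mse = float(np.mean(err**2))
            self.n_iterations_ = it
            self.final_mse_ = mse
            if mse <= cfg.target_mse:
                break
            # backpropagation of the MSE through both sigmoid layers
            delta_out = (2.0 / n) * err * out * (1.0 - out)
            g_w2 = hid.T @ delta_out
            g_b2 = float(delta_out.sum())
            delta_hid = np.outer(delta_out, self.w2) * hid * (1.0 - hid)
            g_w1 = Xs.T @ delta_hid
            g_b1 = delta_hid.sum(axis=0)

            grads = [g_w1, g_b1, g_w2, g_b2]
            step = cfg.learning_rate * np.sqrt(1 - beta2**it) / (1 - beta1**it)
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * (g * g if i < 3 else g**2)
                if i < 3:
                    params[i] -= step * m[i] / (np.sqrt(v[i]) + eps)
                else:
                    self.b2 -= step * m[i] / (np.sqrt(v[i]) + eps)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.w1 is None:
            raise RuntimeError("model is not fitted")
        Xs = self._prepare(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        if Xs.shape[1] != self.w1.shape[0]:
            raise ValueError(
                f"feature dimension {Xs.shape[1]} != trained {self.w1.shape[0]}"
            )
        return self._forward(Xs)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(np.int64)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        if self.w1 is None:
            raise RuntimeError("model is not fitted")
        return {
            "model": "mlp",
            "config": self.config.__dict__,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "mu": None if self._mu is None else self._mu.tolist(),
            "sd": None if self._sd is None else self._sd.tolist(),
            "n_iterations": self.n_iterations_,
            "final_mse": self.final_mse_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        model = cls(MLPConfig(**d["config"]))
        model.w1 = np.asarray(d["w1"], dtype=np.float64)
        model.b1 = np.asarray(d["b1"], dtype=np.float64)
        model.w2 = np.asarray(d["w2"], dtype=np.float64)
        model.b2 = float(d["b2"])
        model._mu = None if d["mu"] is None else np.asarray(d["mu"])
        model._sd = None if d["sd"] is None else np.asarray(d["sd"])
        model.n_iterations_ = d.get("n_iterations", 0)
        model.final_mse_ = d.get("final_mse", float("nan"))
        return model


class LinearSVM:
    """Support-vector machine with an explicit dual-form decision function."""

    def __init__(self, C: float = 1.0, seed: int | None = None) -> None:
        self.C = C
        self.seed = seed
        self.support_vectors_: np.ndarray | None = None
        self.dual_weights_: np.ndarray | None = None
        self.bias_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        svc = SVC(kernel="linear", C=self.C, random_state=self.seed)
        svc.fit(X, y)
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_weights_ = svc.dual_coef_.ravel().copy()
        self.bias_ = float(svc.intercept_[0])
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.support_vectors_ is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.support_vectors_.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != "
                f"trained {self.support_vectors_.shape[1]}"
            )
        return X @ self.support_vectors_.T @ self.dual_weights_ + self.bias_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) >= 0).astype(np.int64)

    def to_dict(self) -> dict:
        if self.support_vectors_ is None:
            raise RuntimeError("model is not fitted")
        return {
            "model": "svm",
            "config": {"C": self.C, "seed": self.seed},
            "support_vectors": self.support_vectors_.tolist(),
            "dual_weights": self.dual_weights_.tolist(),
            "bias": self.bias_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVM":
        model = cls(**d["config"])
        model.support_vectors_ = np.asarray(d["support_vectors"], dtype=np.float64)
        model.dual_weights_ = np.asarray(d["dual_weights"], dtype=np.float64)
        model.bias_ = float(d["bias"])
        return model


@dataclass
class KNN:
    """k-nearest-neighbor majority vote under the Euclidean metric."""

    k: int = 5
    X_: np.ndarray | None = field(default=None, repr=False)
    y_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNN":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel().astype(np.int64)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self.X_ = X
        self.y_ = y
        return self

    def _neighbor_labels(self, X: np.ndarray) -> np.ndarray:
        if self.X_ is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        dist = cdist(X, self.X_)
        # stable sort: equal distances resolved by training-set order
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        return self.y_[order]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of the k neighbors belonging to the positive class."""
        return self._neighbor_labels(X).mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(np.int64)

    def vote_score(self, X: np.ndarray) -> np.ndarray:
        """Winning-class vote fraction, in (0.5, 1] for odd k."""
        frac_pos = self.decision_scores(X)
        return np.maximum(frac_pos, 1.0 - frac_pos)

    def to_dict(self) -> dict:
        if self.X_ is None:
            raise RuntimeError("model is not fitted")
        return {
            "model": "knn",
            "config": {"k": self.k},
            "X": self.X_.tolist(),
            "y": self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KNN":
        model = cls(**d["config"])
        model.X_ = np.asarray(d["X"], dtype=np.float64)
        model.y_ = np.asarray(d["y"], dtype=np.int64)
        return model


_REGISTRY = {"mlp": MLP, "svm": LinearSVM, "knn": KNN}


def make_classifier(name: str, seed: int | None = None, **kwargs):
    """Instantiate a classifier by name ('mlp', 'svm' or 'knn')."""
    name = name.lower()
    if name not in _REGISTRY:
        raise ValueError(f"unknown classifier {name!r}; choose from {sorted(_REGISTRY)}")
    if name == "mlp":
        return MLP(MLPConfig(seed=0 if seed is None else seed, **kwargs))
    if name == "svm":
        return LinearSVM(seed=seed, **kwargs)
    return KNN(**kwargs)


def model_from_dict(d: dict):
    """Rebuild a serialized classifier from its dictionary form."""
    kind = d.get("model")
    if kind == "mlp":
        return MLP.from_dict(d)
    if kind == "svm":
        return LinearSVM.from_dict(d)
    if kind == "knn":
        return KNN.from_dict(d)
    raise ValueError(f"unknown serialized model kind {kind!r}")
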