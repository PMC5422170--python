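"""Seed-variety classifiers and confusion-matrix evaluation.

Two classifiers operate on the seven-feature vector:

* a one-hidden-layer backpropagation neural network (BPNN) with
  logistic-sigmoid activations, trained by online gradient descent on
  squared error until the epoch-mean MSE drops below a tolerance.  The
  hidden-layer size follows the sizing rule ``n_h = n_i + n_o + k`` with
  ``k`` in {-2, 0, 2};
* a Gaussian Bayes classifier: full-covariance class-conditional
  Gaussians (quadratic discriminant) with count-proportional priors and
  a small ridge on each covariance.

Evaluation is by confusion matrix with rows = predicted and columns =
true class; per-class accuracy is the diagonal count over the true-class
column total, reported as a percentage rounded to 2 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import PaddyIdError
from .features import FEATURE_NAMES, N_FEATURES, NormalizationRanges

__all__ = [
    "TrainConfig",
    "BPNNModel",
    "BayesModel",
    "ConfusionMatrix",
    "hidden_nodes",
    "train_bpnn",
    "predict_bpnn",
    "train_bayes",
    "predict_bayes",
    "evaluate",
    "save_model",
    "load_model",
]


def hidden_nodes(n_i: int, n_o: int, k: int) -> int:
    """Hidden-layer node count from the sizing rule ``n_i + n_o + k``."""
    if n_i < 1 or n_o < 1:
        raise PaddyIdError("n_i and n_o must be at least 1")
    if k not in (-2, 0, 2):
        raise PaddyIdError(f"k must be in {{-2, 0, 2}}, got {k}")
    n_h = n_i + n_o + k
    if n_h < 1:
        raise PaddyIdError(f"hidden node count {n_h} < 1")
    return n_h


@dataclass
class TrainConfig:
    """Training regime of the BPNN.

    ``learning_rate`` and ``tolerance_mse`` default to 0.01; training
    stops when the epoch-mean squared error (over samples and output
    nodes) falls below the tolerance, or at ``max_epochs``.
    """

    learning_rate: float = 0.01
    tolerance_mse: float = 0.01
    k: int = 0
    max_epochs: int = 10_000
    rng_seed: int = 0
    activation: str = "logistic"  # or "tanh"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.tolerance_mse <= 0:
            raise PaddyIdError("learning_rate and tolerance_mse must be positive")
        if self.activation not in ("logistic", "tanh"):
            raise PaddyIdError(f"unknown activation {self.activation!r}")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "tolerance_mse": self.tolerance_mse,
            "k": self.k,
            "max_epochs": self.max_epochs,
            "rng_seed": self.rng_seed,
            "activation": self.activation,
        }


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-x))
    return np.tanh(x)


def _act_deriv(y: np.ndarray, kind: str) -> np.ndarray:
    """Derivative expressed through the activation value itself."""
    if kind == "logistic":
        return y * (1.0 - y)
    return 1.0 - y * y


@dataclass
class BPNNModel:
    """Weights and metadata of a trained one-hidden-layer network."""

    labels: list[str]
    W_ij: np.ndarray  # (n_h, n_i) input -> hidden
    b_ij: np.ndarray  # (n_h,)
    W_jk: np.ndarray  # (n_o, n_h) hidden -> output
    b_jk: np.ndarray  # (n_o,)
    activation: str = "logistic"
    ranges: NormalizationRanges | None = None
    config: TrainConfig | None = None
    converged: bool = True
    epochs_run: int = 0
    final_mse: float = float("nan")
    log: list[tuple[int, float]] = field(default_factory=list, repr=False)

    @property
    def n_i(self) -> int:
        return self.W_ij.shape[1]

    @property
    def n_h(self) -> int:
        return self.W_ij.shape[0]

    @property
    def n_o(self) -> int:
        return self.W_jk.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = _act(self.W_ij @ x + self.b_ij, self.activation)
        return _act(self.W_jk @ h + self.b_jk, self.activation)


def train_bpnn(X, y, cfg: TrainConfig | None = None,
               ranges: NormalizationRanges | None = None) -> BPNNModel:
    """Train the BPNN by online (per-sample) gradient descent.

    ``X`` holds normalized feature vectors in [0, 1]; ``y`` the class
    labels.  Samples are visited in a fixed shuffled order drawn from
    ``cfg.rng_seed`` each epoch, targets are one-hot, and weights are
    initialized uniformly in [-0.5, 0.5] from the same seed, so a fixed
    seed and data give a bitwise-identical weight trajectory.  If the
    tolerance is not reached by ``max_epochs`` the model is returned
    with ``converged=False``.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise PaddyIdError("X must be a 2-D array of feature vectors")
    if not np.isfinite(X).all():
        raise PaddyIdError("non-finite values in training inputs")
    y = np.asarray(y)
    if len(y) != len(X):
        raise PaddyIdError("X and y length mismatch")
    labels = sorted(set(map(str, y)))
    if len(labels) < 2:
        raise PaddyIdError("need at least two classes")
    lab_index = {l: i for i, l in enumerate(labels)}
    yi = np.array([lab_index[str(v)] for v in y])
    n, n_i = X.shape
    n_o = len(labels)
    n_h = hidden_nodes(n_i, n_o, cfg.k)
    targets = np.eye(n_o)[yi]

    rng = np.random.default_rng(cfg.rng_seed)
    W_ij = rng.uniform(-0.5, 0.5, size=(n_h, n_i))
    b_ij = rng.uniform(-0.5, 0.5, size=n_h)
    W_jk = rng.uniform(-0.5, 0.5, size=(n_o, n_h))
    b_jk = rng.uniform(-0.5, 0.5, size=n_o)

    lr, act = cfg.learning_rate, cfg.activation
    log: list[tuple[int, float]] = []
    converged = False
    epoch = 0
    mse = float("inf")
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        sq_sum = 0.0
        for idx in order:
            x = X[idx]
            t = targets[idx]
            h = _act(W_ij @ x + b_ij, act)
            o = _act(W_jk @ h + b_jk, act)
            err = o - t
            sq_sum += float(err @ err)
            delta_o = err * _act_deriv(o, act)
            delta_h = (W_jk.T @ delta_o) * _act_deriv(h, act)
            W_jk -= lr * np.outer(delta_o, h)
            b_jk -= lr * delta_o
            W_ij -= lr * np.outer(delta_h, x)
            b_ij -= lr * delta_h
        mse = sq_sum / (n * n_o)
        log.append((epoch, mse))
        if mse < cfg.tolerance_mse:
            converged = True
            break

    return BPNNModel(
        labels=labels,
        W_ij=W_ij,
        b_ij=b_ij,
        W_jk=W_jk,
        b_jk=b_jk,
        activation=act,
        ranges=ranges,
        config=cfg,
        converged=converged,
        epochs_run=epoch,
        final_mse=mse,
        log=log,
    )


def predict_bpnn(m: BPNNModel, v) -> tuple[str, np.ndarray]:
    """Predict the label of one feature vector; returns (label, activations).

    If the model carries normalization ranges the raw feature vector is
    normalized first; otherwise the input must already be normalized.
    Ties in the output activations break toward the earlier label.
    """
    x = np.asarray(v, dtype=np.float64)
    if x.shape != (m.n_i,):
        raise PaddyIdError(f"expected {m.n_i} features, got shape {x.shape}")
    if m.ranges is not None:
        from .features import apply_normalization

        x = apply_normalization(x, m.ranges)
    o = m.forward(x)
    return m.labels[int(np.argmax(o))], o


@dataclass
class BayesModel:
    """Gaussian class-conditional model (quadratic discriminant)."""

    labels: list[str]
    means: np.ndarray       # (n_classes, d)
    covariances: np.ndarray  # (n_classes, d, d), ridge-regularized
    priors: np.ndarray      # (n_classes,), sums to 1
    _chol: np.ndarray | None = field(default=None, repr=False)

    def log_posteriors(self, x: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior of each class at x."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.means.shape[1],):
            raise PaddyIdError(f"expected {self.means.shape[1]} features")
        out = np.empty(len(self.labels))
        for i in range(len(self.labels)):
            L = np.linalg.cholesky(self.covariances[i])
            z = np.linalg.solve(L, x - self.means[i])
            logdet = 2.0 * np.log(np.diag(L)).sum()
            out[i] = np.log(self.priors[i]) - 0.5 * (logdet + z @ z)
        return out


def train_bayes(X, y, ridge_scale: float = 1e-6) -> BayesModel:
    """Fit a Gaussian per class with count-proportional priors.

    Each class covariance receives a ridge ``ridge_scale * trace / d``
    on its diagonal; a covariance that is still not positive definite
    raises.  Every class needs at least two samples.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray([str(v) for v in y])
    labels = sorted(set(y))
    d = X.shape[1]
    means = np.empty((len(labels), d))
    covs = np.empty((len(labels), d, d))
    priors = np.empty(len(labels))
    for i, lab in enumerate(labels):
        xs = X[y == lab]
        if len(xs) < 2:
            raise PaddyIdError(f"class {lab!r} has fewer than 2 samples")
        means[i] = xs.mean(axis=0)
        cov = np.cov(xs, rowvar=False)
        cov = cov + np.eye(d) * (ridge_scale * np.trace(cov) / d)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise PaddyIdError(f"singular covariance for class {lab!r}") from exc
        covs[i] = cov
        priors[i] = len(xs)
    priors /= priors.sum()
    return BayesModel(labels=labels, means=means, covariances=covs, priors=priors)


def predict_bayes(m: BayesModel, v) -> str:
    """Maximum-posterior label; ties break toward the earlier label."""
    return m.labels[int(np.argmax(m.log_posteriors(np.asarray(v, dtype=np.float64))))]


@dataclass
class ConfusionMatrix:
    """Counts with rows = predicted class and columns = true class."""

    labels: list[str]
    counts: np.ndarray  # (n, n) int, [predicted, true]
    #: optional per-true-class totals to use as accuracy denominators
    #: (for externally reported tables whose columns do not sum to the
    #: stated totals); defaults to the column sums
    column_totals: np.ndarray | None = None

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = [str(v) for v in y_true]
        y_pred = [str(v) for v in y_pred]
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        labels = list(labels)
        idx = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            if t not in idx or p not in idx:
                raise PaddyIdError(f"unknown label {t!r}/{p!r}")
            counts[idx[p], idx[t]] += 1
        return cls(labels=labels, counts=counts)

    def to_dict(self) -> dict:
        d = {"labels": list(self.labels), "counts": self.counts.tolist()}
        if self.column_totals is not None:
            d["column_totals"] = [int(v) for v in self.column_totals]
        return d


def evaluate(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class and average classification accuracy in percent.

    Per-class accuracy is the diagonal count over the true-class column
    total; average accuracy is the trace over the grand total.  Values
    are rounded to 2 decimals for reporting.  A zero column total
    raises.
    """
    counts = np.asarray(cm.counts, dtype=np.float64)
    totals = (
        counts.sum(axis=0)
        if cm.column_totals is None
        else np.asarray(cm.column_totals, dtype=np.float64)
    )
    if (totals <= 0).any():
        raise PaddyIdError("zero column total in confusion matrix")
    per_class = np.round(100.0 * np.diag(counts) / totals, 2)
    average = round(100.0 * np.trace(counts) / totals.sum(), 2)
    return per_class, float(average)


# ---------------------------------------------------------------------------
# serialization

def _model_dict(model) -> dict:
    if isinstance(model, BPNNModel):
        return {
            "type": "bpnn",
            "labels": model.labels,
            "activation": model.activation,
            "W_ij": model.W_ij.tolist(),
            "b_ij": model.b_ij.tolist(),
            "W_jk": model.W_jk.tolist(),
            "b_jk": model.b_jk.tolist(),
            "ranges": None if model.ranges is None else model.ranges.to_dict(),
            "config": None if model.config is None else model.config.to_dict(),
            "converged": model.converged,
            "epochs_run": model.epochs_run,
            "final_mse": model.final_mse,
            "feature_names": list(FEATURE_NAMES),
        }
    if isinstance(model, BayesModel):
        return {
            "type": "bayes",
            "labels": model.labels,
            "means": model.means.tolist(),
            "covariances": model.covariances.tolist(),
            "priors": model.priors.tolist(),
            "feature_names": list(FEATURE_NAMES),
        }
    raise PaddyIdError(f"cannot serialize {type(model).__name__}")


def save_model(model, path) -> None:
    """Serialize a trained model to JSON (deterministic byte layout)."""
    with open(path, "w") as fh:
        json.dump(_model_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path):
    """Load a model serialized by :func:`save_model`."""
    with open(path) as fh:
        d = json.load(fh)
    if d.get("feature_names") not in (None, list(FEATURE_NAMES)):
        raise PaddyIdError("feature-order mismatch in serialized model")
    if d["type"] == "bpnn":
        cfg = TrainConfig(**d["config"]) if d.get("config") else None
        ranges = (
            NormalizationRanges.from_dict(d["ranges"]) if d.get("ranges") else None
        )
        return BPNNModel(
            labels=list(d["labels"]),
            W_ij=np.asarray(d["W_ij"], float),
            b_ij=np.asarray(d["b_ij"], float),
            W_jk=np.asarray(d["W_jk"], float),
            b_jk=np.asarray(d["b_jk"], float),
            activation=d.get("activation", "logistic"),
            ranges=ranges,
            config=cfg,
            converged=bool(d.get("converged", True)),
            epochs_run=int(d.get("epochs_run", 0)),
            final_mse=float(d.get("final_mse", float("nan"))),
        )
    if d["type"] == "bayes":
        return BayesModel(
            labels=list(d["labels"]),
            means=np.asarray(d["means"], float),
            covariances=np.asarray(d["covariances"], float),
            priors=np.asarray(d["priors"], float),
        )
    raise PaddyIdError(f"unknown model type {d['type']!r}")
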