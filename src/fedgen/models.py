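"""Trainable models: the parallel-lambda LASSO bank and the MLP ancestry
classifier, both expressed over :class:`ModelParams` so the federated engine
can treat them uniformly.

The LASSO bank ("lassonet") trains one linear model per l1 penalty
``lambda`` in the same pass over the data: the objective per penalty is

    loss = mean((y - X w - b)^2) + lambda * ||w||_1        (intercept free)

optimized by proximal stochastic gradient descent — a gradient step on the
squared-error term followed by soft-thresholding at ``lr * lambda`` — which
produces exact zeros, unlike a subgradient step. Updates are computed
row-by-row so that training the bank is *bit-identical* to training each
single-lambda model separately with the same seed and batch order; the bank
is purely an efficiency and bookkeeping device.

Under this loss convention the null-model threshold is
``lambda_max = 2 max_j |x_j'(y - ybar)| / n`` and, on an orthonormal design
with X'X = n I, the optimum is ``soft(beta_OLS, lambda / 2)``.

The MLP is a fully connected ``20 -> 800 -> 200 -> 26`` network (by
default) with selu activations and raw-score outputs, trained with
cross-entropy; at the default sizes it carries 182,226 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ModelParams",
    "save_checkpoint",
    "load_checkpoint",
    "soft_threshold",
    "lambda_max",
    "make_lambda_grid",
    "lasso_loss",
    "lasso_mse",
    "lasso_train_epoch",
    "LassoBankSpec",
    "LassoBankModel",
    "LassoBankResults",
    "selu",
    "mlp_forward",
    "cross_entropy",
    "count_params",
    "MLPSpec",
    "AncestryMLP",
    "MLPResults",
    "r2_score",
    "accuracy",
]

# ---------------------------------------------------------------------------
# ModelParams


@dataclass
class ModelParams:
    """Flat, ordered collection of named numeric tensors — the unit the
    federated engine averages."""

    kind: str
    tensors: dict[str, np.ndarray]

    def save(self, prefix) -> None:
        """Checkpoint as a named-tensor archive (`<prefix>.npz`) plus a JSON
        manifest (`<prefix>.json`) carrying the kind, tensor order, shapes
        and dtypes; optional metadata (e.g. a lambda grid) may be attached
        via :func:`save_checkpoint`."""
        save_checkpoint(self, prefix)

    @classmethod
    def load(cls, prefix) -> "ModelParams":
        return load_checkpoint(prefix)[0]

    def copy(self) -> "ModelParams":
        return ModelParams(self.kind, {k: v.copy() for k, v in self.tensors.items()})

    @property
    def n_values(self) -> int:
        return sum(v.size for v in self.tensors.values())

    def flatten(self) -> np.ndarray:
        return np.concatenate([v.ravel() for v in self.tensors.values()])

    def unflatten(self, flat: np.ndarray) -> "ModelParams":
        """Rebuild params of this shape from a flat vector (round-trip
        inverse of :meth:`flatten`)."""
        out: dict[str, np.ndarray] = {}
        pos = 0
        for k, v in self.tensors.items():
            out[k] = flat[pos : pos + v.size].reshape(v.shape).copy()
            pos += v.size
        if pos != flat.size:
            raise ValueError("flat vector length does not match parameter count")
        return ModelParams(self.kind, out)


def save_checkpoint(params: ModelParams, prefix, metadata: dict | None = None) -> None:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": params.kind,
        "tensors": {
            k: {"shape": list(v.shape), "dtype": str(v.dtype)}
            for k, v in params.tensors.items()
        },
        "metadata": metadata or {},
    }
    Path(f"{prefix}.json").write_text(json.dumps(manifest, indent=2) + "\n")
    np.savez(f"{prefix}.npz", **params.tensors)


def load_checkpoint(prefix) -> tuple[ModelParams, dict]:
    import json
    from pathlib import Path

    manifest = json.loads(Path(f"{prefix}.json").read_text())
    with np.load(f"{prefix}.npz") as archive:
        tensors = {}
        for name, info in manifest["tensors"].items():
            arr = archive[name]
            if list(arr.shape) != info["shape"] or str(arr.dtype) != info["dtype"]:
                raise ValueError(f"checkpoint tensor {name!r} does not match manifest")
            tensors[name] = arr
    return ModelParams(manifest["kind"], tensors), manifest["metadata"]


def soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


# ---------------------------------------------------------------------------
# LASSO bank


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is all-zero:
    ``2 max_j |x_j'(y - ybar)| / n`` for the mean-squared-error + l1 loss."""
    n = len(y)
    return float(2.0 * np.max(np.abs(X.T @ (y - y.mean()))) / n)


def make_lambda_grid(lam_max: float, n_lambda: int = 32, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from ``lam_max`` down to ``lam_max * ratio``,
    strictly decreasing."""
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0, np.log10(ratio), n_lambda)


def lasso_loss(
    weights: np.ndarray, intercepts: np.ndarray, lambdas: np.ndarray,
    X: np.ndarray, y: np.ndarray,
) -> np.ndarray:
    """Per-lambda penalized training loss (intercept unpenalized)."""
    if X.shape[1] != weights.shape[1]:
        raise ValueError("feature dimension mismatch")
    resid = y[:, None] - X @ weights.T - intercepts[None, :]
    return (resid**2).mean(axis=0) + lambdas * np.abs(weights).sum(axis=1)


def lasso_mse(
    weights: np.ndarray, intercepts: np.ndarray, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-lambda unpenalized prediction MSE (the model-selection loss)."""
    resid = y[:, None] - X @ weights.T - intercepts[None, :]
    return (resid**2).mean(axis=0)


def lasso_train_epoch(
    weights: np.ndarray,
    intercepts: np.ndarray,
    lambdas: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lr: float,
    batch_size: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One pass of proximal SGD over shuffled mini-batches, updating every
    lambda's model on the same batches. Row-by-row updates keep the bank
    bit-identical to independently trained single-lambda models.

    Returns new (weights, intercepts); inputs are not mutated.
    """
    n, p = X.shape
    if weights.shape[1] != p:
        raise ValueError("feature dimension mismatch")
    W = weights.copy()
    b = intercepts.copy()
    if batch_size is None or batch_size >= n:
        batches = [np.arange(n)]
        order = None
    else:
        order = rng.permutation(n)
        batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    for idx in batches:
        Xb, yb = X[idx], y[idx]
        Xbt = Xb.T
        scale = 2.0 / len(idx)
        for l in range(W.shape[0]):
            w = W[l]
            r = Xb @ w + b[l] - yb
            grad_w = scale * (Xbt @ r)
            W[l] = soft_threshold(w - lr * grad_w, lr * lambdas[l])
            b[l] = b[l] - lr * (scale * r.sum())
    if not np.all(np.isfinite(W)):
        bad = int(np.flatnonzero(~np.isfinite(W).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite LASSO weights at lambda index {bad}; "
            "reduce the learning rate"
        )
    return W, b


class LassoBankSpec:
    """Functional interface over a LASSO bank for the federated engine."""

    kind = "lasso_bank"

    def __init__(self, n_features: int, lambdas: np.ndarray) -> None:
        lambdas = np.asarray(lambdas, dtype=np.float64)
        if len(lambdas) > 1 and np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        self.n_features = n_features
        self.lambdas = lambdas

    def init_params(self, seed: int | None = None) -> ModelParams:
        L = len(self.lambdas)
        return ModelParams(
            self.kind,
            {
                "weights": np.zeros((L, self.n_features)),
                "intercepts": np.zeros(L),
            },
        )

    def train_epoch(
        self,
        params: ModelParams,
        data: tuple[np.ndarray, np.ndarray],
        lr: float,
        batch_size: int | None,
        rng: np.random.Generator,
    ) -> ModelParams:
        X, y = data
        W, b = lasso_train_epoch(
            params.tensors["weights"], params.tensors["intercepts"],
            self.lambdas, X, y, lr, batch_size, rng,
        )
        return ModelParams(self.kind, {"weights": W, "intercepts": b})

    def val_loss(self, params: ModelParams, data: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        X, y = data
        return lasso_mse(params.tensors["weights"], params.tensors["intercepts"], X, y)

    def train_loss(self, params: ModelParams, data) -> float:
        X, y = data
        return float(
            lasso_loss(
                params.tensors["weights"], params.tensors["intercepts"],
                self.lambdas, X, y,
            ).min()
        )

    def predict(self, params: ModelParams, X: np.ndarray, lambda_index: int) -> np.ndarray:
        return X @ params.tensors["weights"][lambda_index] + params.tensors["intercepts"][lambda_index]


class LassoBankModel:
    """LASSO regularization-path model on standardized features.

    Parameters
    ----------
    X, y : arrays
        Training design (already column-standardized) and response.
    lambdas : array or None
        Strictly decreasing penalty grid; by default 32 log-spaced values
        from lambda_max down to lambda_max * 1e-3.
    """

    def __init__(
        self, X: np.ndarray, y: np.ndarray,
        lambdas: np.ndarray | None = None, n_lambda: int = 32,
    ) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        if lambdas is None:
            lambdas = make_lambda_grid(lambda_max(self.X, self.y), n_lambda)
        self.spec = LassoBankSpec(self.X.shape[1], lambdas)

    def fit(
        self,
        epochs: int = 256,
        lr: float = 5e-3,
        decay: float = 0.99,
        batch_size: int | None = 16,
        seed: int = 0,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "LassoBankResults":
        rng = np.random.default_rng(seed)
        params = self.spec.init_params()
        for epoch in range(epochs):
            params = self.spec.train_epoch(
                params, (self.X, self.y), lr * decay**epoch, batch_size, rng
            )
        if X_val is None:
            X_val, y_val = self.X, self.y
        val = self.spec.val_loss(params, (X_val, y_val))
        best = _argmin_prefer_larger_lambda(val)
        return LassoBankResults(
            spec=self.spec, params=params, val_mse=val, selected=best
        )


def _argmin_prefer_larger_lambda(losses: np.ndarray) -> int:
    """Index of the minimum; ties go to the larger lambda (smaller index,
    the grid being decreasing)."""
    return int(np.argmin(losses))


@dataclass
class LassoBankResults:
    """Fitted bank: coefficient matrix over the penalty grid, validation
    MSE per lambda and the selected path point."""

    spec: LassoBankSpec
    params: ModelParams
    val_mse: np.ndarray
    selected: int

    @property
    def coef_path(self) -> np.ndarray:
        return self.params.tensors["weights"]

    @property
    def coef_(self) -> np.ndarray:
        return self.coef_path[self.selected]

    @property
    def intercept_(self) -> float:
        return float(self.params.tensors["intercepts"][self.selected])

    def predict(self, X: np.ndarray, lambda_index: int | None = None) -> np.ndarray:
        idx = self.selected if lambda_index is None else lambda_index
        return self.spec.predict(self.params, X, idx)

    def summary(self) -> str:
        lam = self.spec.lambdas
        nnz = (self.coef_path != 0).sum(axis=1)
        lines = [
            "LASSO bank (proximal SGD)",
            f"  lambdas: {len(lam)}  features: {self.spec.n_features}",
            f"  selected lambda = {lam[self.selected]:.5g} "
            f"(index {self.selected}, {nnz[self.selected]} nonzero)",
            f"  validation MSE at selection = {self.val_mse[self.selected]:.5g}",
            "  lambda      val_mse     nonzero",
        ]
        for i in range(len(lam)):
            mark = " *" if i == self.selected else ""
            lines.append(f"  {lam[i]:<11.4g} {self.val_mse[i]:<11.5g} {nnz[i]}{mark}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# MLP ancestry classifier

_SELU_SCALE = 1.0507009873554804934193349852946
_SELU_ALPHA = 1.6732632423543772848170429916717


def selu(x: np.ndarray) -> np.ndarray:
    # exp only on the negative branch; avoids overflow for large inputs
    neg = _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))
    return _SELU_SCALE * np.where(x > 0, x, neg)


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(
        x > 0, np.ones((), dtype=x.dtype), _SELU_ALPHA * np.exp(np.minimum(x, 0.0))
    )


def count_params(n_in: int, hidden: tuple[int, ...], n_out: int) -> int:
    """Total weight + bias count of the fully connected architecture."""
    sizes = (n_in, *hidden, n_out)
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def mlp_forward(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Raw class scores: affine -> selu -> affine -> selu -> affine."""
    t = params.tensors
    n_layers = len(t) // 2
    a = np.asarray(X, dtype=t["W0"].dtype)
    if a.shape[1] != t["W0"].shape[0]:
        raise ValueError("input width does not match the first layer")
    for i in range(n_layers):
        a = a @ t[f"W{i}"] + t[f"b{i}"]
        if i < n_layers - 1:
            a = selu(a)
    return a


def cross_entropy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean over samples of -log softmax(score)[label]."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= scores.shape[1]:
        raise ValueError("labels out of range for the score matrix")
    lse = logsumexp(scores, axis=1)
    picked = scores[np.arange(len(labels)), labels]
    return float(np.mean(lse - picked))


class MLPSpec:
    """Fully connected selu classifier over ModelParams.

    Parameters and activations are kept in single precision by default: the
    classifier reads 20-dimensional PC scores and its accuracy is nowhere
    near the float32 resolution, while training throughput roughly doubles.
    """

    kind = "mlp"

    def __init__(
        self, n_in: int = 20, hidden: tuple[int, ...] = (800, 200), n_out: int = 26,
        dtype=np.float32,
    ) -> None:
        self.sizes = (n_in, *hidden, n_out)
        self.dtype = dtype

    def init_params(self, seed: int | None = 0) -> ModelParams:
        """Variance-scaling (LeCun normal) initialization, seeded."""
        rng = np.random.default_rng(seed)
        tensors: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            tensors[f"W{i}"] = rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b)).astype(self.dtype)
            tensors[f"b{i}"] = np.zeros(b, dtype=self.dtype)
        return ModelParams(self.kind, tensors)

    def _loss_and_grad(
        self, params: ModelParams, X: np.ndarray, labels: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        t = params.tensors
        n_layers = len(self.sizes) - 1
        acts = [np.asarray(X, dtype=self.dtype)]
        pre: list[np.ndarray] = []
        a = acts[0]
        for i in range(n_layers):
            z = a @ t[f"W{i}"] + t[f"b{i}"]
            pre.append(z)
            a = selu(z) if i < n_layers - 1 else z
            acts.append(a)
        scores = acts[-1]
        n = len(labels)
        lse = logsumexp(scores, axis=1)
        loss = float(np.mean(lse - scores[np.arange(n), labels]))
        prob = np.exp(scores - lse[:, None])
        delta = prob
        delta[np.arange(n), labels] -= 1.0
        delta /= n
        grads: dict[str, np.ndarray] = {}
        for i in reversed(range(n_layers)):
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ t[f"W{i}"].T) * _selu_grad(pre[i - 1])
        return loss, grads

    def train_epoch(
        self,
        params: ModelParams,
        data: tuple[np.ndarray, np.ndarray],
        lr: float,
        batch_size: int | None,
        rng: np.random.Generator,
    ) -> ModelParams:
        X, labels = data
        X = np.asarray(X, dtype=self.dtype)
        n = len(labels)
        new = params.copy()
        if batch_size is None or batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
        lr = self.dtype(lr)
        for idx in batches:
            _, grads = self._loss_and_grad(new, X[idx], labels[idx])
            for k in new.tensors:
                new.tensors[k] -= lr * grads[k]
        return new

    def val_loss(self, params: ModelParams, data: tuple[np.ndarray, np.ndarray]) -> float:
        X, labels = data
        return cross_entropy(mlp_forward(params, X), labels)

    train_loss = val_loss

    def predict(self, params: ModelParams, X: np.ndarray) -> np.ndarray:
        return np.argmax(mlp_forward(params, X), axis=1)


class AncestryMLP:
    """MLP classifier from PC scores to population labels (statsmodels-style
    wrapper around :class:`MLPSpec` for centralized/local training)."""

    def __init__(
        self, X: np.ndarray, labels: np.ndarray,
        hidden: tuple[int, ...] = (800, 200), n_classes: int | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        n_classes = n_classes or int(self.labels.max()) + 1
        self.spec = MLPSpec(self.X.shape[1], hidden, n_classes)

    def fit(
        self,
        epochs: int = 512,
        lr: float = 0.1,
        decay: float = 0.9999,
        batch_size: int | None = 64,
        seed: int = 0,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPResults":
        rng = np.random.default_rng(seed)
        params = self.spec.init_params(seed)
        history = []
        for epoch in range(epochs):
            params = self.spec.train_epoch(
                params, (self.X, self.labels), lr * decay**epoch, batch_size, rng
            )
            if X_val is not None and (epoch + 1) % max(1, epochs // 64) == 0:
                history.append(
                    (epoch + 1, self.spec.val_loss(params, (X_val, y_val)))
                )
        return MLPResults(spec=self.spec, params=params, history=history)


@dataclass
class MLPResults:
    spec: MLPSpec
    params: ModelParams
    history: list[tuple[int, float]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.spec.predict(self.params, X)

    def score(self, X: np.ndarray, labels: np.ndarray) -> float:
        return accuracy(labels, self.predict(X))

    def summary(self) -> str:
        sizes = self.spec.sizes
        lines = [
            "MLP classifier (selu, cross-entropy, SGD)",
            f"  architecture: {' -> '.join(map(str, sizes))}"
            f"  ({self.params.n_values} parameters)",
        ]
        if self.history:
            lines.append(f"  final validation loss = {self.history[-1][1]:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# metrics


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) < 2:
        raise ValueError("need at least two samples")
    tss = float(((y_true - y_true.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("R^2 undefined for a zero-variance response")
    rss = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - rss / tss


def accuracy(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(labels_true == labels_pred))
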