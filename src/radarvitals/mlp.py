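"""Small sigmoid MLP trained with the Levenberg-Marquardt algorithm.

Architecture: dense sigmoid layers of 8, 16 and 1 units on the
7-dimensional RR-feature vector (five HRV statistics + age + gender);
225 trainable parameters.  The loss is the mean squared error of the
single sigmoid output against 0/1 labels.

Levenberg-Marquardt solves, per iteration (epoch),

    delta = -(J^T J + mu I)^(-1) J^T r

with J the Jacobian of per-example residuals r and mu the adaptive
damping: a step is accepted only if the training MSE decreases, otherwise
mu is multiplied by ``mu_factor`` and the step recomputed; on acceptance
mu is divided by ``mu_factor``.  mu -> 0 recovers Gauss-Newton, mu -> inf
a scaled gradient step.  Early stopping checkpoints the best-validation
parameters (ties keep the earlier epoch).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidArgumentError, SingleClassError

DEFAULT_LAYER_SIZES = (8, 16, 1)
DEFAULT_INPUT_DIM = 7
DEFAULT_MU0 = 1e-3
DEFAULT_MU_FACTOR = 10.0
MU_MAX = 1e10
GRADIENT_FLOOR = 1e-12


class StopReason(str, enum.Enum):
    MAX_EPOCHS = "max_epochs"
    EARLY_STOP = "early_stop"
    GRADIENT_FLOOR = "gradient_floor"
    CONVERGENCE_FAILURE = "convergence_failure"


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Min-max scaling to [0, 1], fit on the training split only."""

    data_min: np.ndarray | None = None
    data_max: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.data_min = X.min(axis=0)
        self.data_max = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.data_min is None:
            raise InvalidArgumentError("scaler not fitted")
        span = np.where(
            self.data_max - self.data_min > 0, self.data_max - self.data_min, 1.0
        )
        return (np.asarray(X, dtype=float) - self.data_min) / span


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class MLPModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    input_dim: int = DEFAULT_INPUT_DIM
    init_seed: int | None = None
    scaler: MinMaxScaler | None = None

    def __post_init__(self) -> None:
        dims = (self.input_dim, *self.layer_sizes)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[i], dims[i + 1]) or b.shape != (dims[i + 1],):
                raise InvalidArgumentError(
                    f"layer {i} shapes inconsistent with sizes {dims}"
                )
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise InvalidArgumentError("non-finite parameters")

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in [0,1]; X is (n, input_dim) or (input_dim,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise InvalidArgumentError(
                f"expected {self.input_dim} features, got {X.shape[1]}"
            )
        a = X
        for w, b in zip(self.weights, self.biases):
            a = sigmoid(a @ w + b)
        return a[:, 0]

    def forward_all(self, X: np.ndarray) -> list[np.ndarray]:
        """All layer activations (input first), for backpropagation."""
        acts = [np.atleast_2d(np.asarray(X, dtype=float))]
        for w, b in zip(self.weights, self.biases):
            acts.append(sigmoid(acts[-1] @ w + b))
        return acts

    # -- flat parameter vector ------------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    def set_params(self, theta: np.ndarray) -> None:
        pos = 0
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos : pos + w.size].reshape(w.shape)
            pos += w.size
            self.biases[i] = theta[pos : pos + b.size].copy()
            pos += b.size
        if pos != len(theta):
            raise InvalidArgumentError("parameter vector length mismatch")

    def copy(self) -> "MLPModel":
        return MLPModel(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            layer_sizes=self.layer_sizes,
            input_dim=self.input_dim,
            init_seed=self.init_seed,
            scaler=self.scaler,
        )

    # -- serialization --------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "input_dim": self.input_dim,
            "init_seed": self.init_seed,
            "params": self.get_params().tolist(),
            "scaler_min": None
            if self.scaler is None or self.scaler.data_min is None
            else self.scaler.data_min.tolist(),
            "scaler_max": None
            if self.scaler is None or self.scaler.data_max is None
            else self.scaler.data_max.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        payload = json.loads(text)
        model = init_network(
            input_dim=payload["input_dim"],
            seed=payload["init_seed"] or 0,
            layer_sizes=tuple(payload["layer_sizes"]),
        )
        model.set_params(np.asarray(payload["params"], dtype=float))
        if payload["scaler_min"] is not None:
            model.scaler = MinMaxScaler(
                np.asarray(payload["scaler_min"]), np.asarray(payload["scaler_max"])
            )
        return model


def init_network(
    input_dim: int = DEFAULT_INPUT_DIM,
    seed: int = 0,
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES,
) -> MLPModel:
    """Weights ~ Normal(0, 1/fan_in), biases zero; deterministic per seed."""
    if input_dim < 1:
        raise InvalidArgumentError("input_dim must be >= 1")
    rng = np.random.default_rng(seed)
    dims = (input_dim, *layer_sizes)
    weights = [
        rng.normal(0.0, 1.0 / math.sqrt(dims[i]), size=(dims[i], dims[i + 1]))
        for i in range(len(layer_sizes))
    ]
    biases = [np.zeros(dims[i + 1]) for i in range(len(layer_sizes))]
    return MLPModel(weights, biases, tuple(layer_sizes), input_dim, seed)


# ---------------------------------------------------------------------------
# residuals and Jacobian
# ---------------------------------------------------------------------------

def residuals_and_jacobian(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-example residuals r_i = yhat_i - y_i and Jacobian dr/dtheta.

    Backpropagation through the sigmoid layers, vectorized over examples;
    column order matches :meth:`MLPModel.get_params`.
    """
    acts = model.forward_all(X)
    yhat = acts[-1][:, 0]
    r = yhat - np.asarray(y, dtype=float)
    n = len(r)
    # delta[l] = d yhat / d z_l, shape (n, units_l)
    deltas: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    a_out = acts[-1]
    deltas[-1] = a_out * (1.0 - a_out)  # (n, 1)
    for l in range(len(model.weights) - 2, -1, -1):
        a = acts[l + 1]
        deltas[l] = (deltas[l + 1] @ model.weights[l + 1].T) * a * (1.0 - a)
    blocks = []
    for l, delta in enumerate(deltas):
        a_prev = acts[l]
        jw = np.einsum("ni,nj->nij", a_prev, delta).reshape(n, -1)
        blocks.append(jw)
        blocks.append(delta)
    return r, np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core
# ---------------------------------------------------------------------------

def lm_step(J: np.ndarray, r: np.ndarray, mu: float) -> np.ndarray:
    """Damped normal-equations step delta = -(J^T J + mu I)^(-1) J^T r."""
    jtj = J.T @ J
    jtr = J.T @ r
    a = jtj + mu * np.eye(jtj.shape[0])
    try:
        return -np.linalg.solve(a, jtr)
    except np.linalg.LinAlgError:
        return -np.linalg.lstsq(a, jtr, rcond=None)[0]


def levenberg_marquardt(
    residual_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    theta0: np.ndarray,
    max_iter: int = 10,
    mu0: float = DEFAULT_MU0,
    mu_factor: float = DEFAULT_MU_FACTOR,
    mu_max: float = MU_MAX,
) -> tuple[np.ndarray, list[float], StopReason]:
    """Generic LM loop on a residual function returning (r, J).

    Returns the final parameters, the accepted-step SSE/2n trajectory and
    the stop reason.  Used directly by :func:`train_lm` and, on
    linear-in-parameter problems, reaches the least-squares optimum in one
    accepted step.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    r, J = residual_fn(theta)
    mse = float(np.mean(r**2))
    history = [mse]
    mu = mu0
    for _ in range(max_iter):
        accepted = False
        while mu <= mu_max:
            cand = theta + lm_step(J, r, mu)
            r_new, J_new = residual_fn(cand)
            mse_new = float(np.mean(r_new**2))
            if mse_new < mse:
                theta, r, J, mse = cand, r_new, J_new, mse_new
                mu = mu / mu_factor
                accepted = True
                break
            mu *= mu_factor
        if not accepted:
            return theta, history, StopReason.CONVERGENCE_FAILURE
        history.append(mse)
        if np.linalg.norm(J.T @ r) < GRADIENT_FLOOR:
            return theta, history, StopReason.GRADIENT_FLOOR
    return theta, history, StopReason.MAX_EPOCHS


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(math.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def split_dataset(
    items: Sequence,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/validation/test split.

    Sizes follow largest-remainder rounding of n * fractions; when
    ``labels`` contains both classes the rounding and shuffling are applied
    within each class (stratification).  Deterministic for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError("fractions must sum to 1")
    n = len(items)
    if n < 7:
        raise InvalidArgumentError("need >= 7 examples to split 70/15/15")
    rng = np.random.default_rng(seed)
    splits: tuple[list, list, list] = ([], [], [])
    if labels is not None and len(set(labels)) > 1:
        labels = np.asarray(labels)
        strata = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    else:
        strata = [np.arange(n)]
    for stratum in strata:
        order = rng.permutation(stratum)
        sizes = _largest_remainder(len(order), fractions)
        pos = 0
        for k, size in enumerate(sizes):
            splits[k].extend(items[i] for i in order[pos : pos + size])
            pos += size
    if any(len(s) == 0 for s in splits):
        raise InvalidArgumentError("a split received 0 examples")
    return splits


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    gradient_norm: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: StopReason = StopReason.MAX_EPOCHS


def train_lm(
    model: MLPModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    max_epochs: int = 10,
    patience: int = 10,
    mu0: float = DEFAULT_MU0,
    mu_factor: float = DEFAULT_MU_FACTOR,
) -> tuple[MLPModel, TrainingHistory]:
    """Levenberg-Marquardt training with best-validation checkpointing.

    One epoch = one accepted LM step (the damping retries within an epoch
    do not count).  The accepted-step training MSE sequence is strictly
    decreasing by construction.  Returns the parameters of the epoch with
    the lowest validation MSE (training MSE when no validation set is
    given; ties keep the earlier epoch).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(X_train) == 0:
        raise InvalidArgumentError("empty training set")
    if not np.all(np.isfinite(X_train)):
        raise InvalidArgumentError("non-finite training features")
    have_val = X_val is not None and len(X_val) > 0
    work = model.copy()
    history = TrainingHistory()

    def val_mse_of(m: MLPModel) -> float:
        if not have_val:
            return float(np.mean((m.forward(X_train) - y_train) ** 2))
        return float(np.mean((m.forward(X_val) - np.asarray(y_val)) ** 2))

    r, J = residuals_and_jacobian(work, X_train, y_train)
    mse = float(np.mean(r**2))
    best = work.copy()
    best_val = val_mse_of(work)
    best_epoch = 0
    mu = mu0
    stop = StopReason.MAX_EPOCHS
    epochs_since_best = 0
    for epoch in range(1, max_epochs + 1):
        theta = work.get_params()
        accepted = False
        while mu <= MU_MAX:
            work.set_params(theta + lm_step(J, r, mu))
            r_new, J_new = residuals_and_jacobian(work, X_train, y_train)
            mse_new = float(np.mean(r_new**2))
            if mse_new < mse:
                r, J, mse = r_new, J_new, mse_new
                mu /= mu_factor
                accepted = True
                break
            mu *= mu_factor
        if not accepted:
            work.set_params(theta)
            stop = StopReason.CONVERGENCE_FAILURE
            break
        vmse = val_mse_of(work)
        history.train_mse.append(mse)
        history.val_mse.append(vmse)
        history.gradient_norm.append(float(np.linalg.norm(2.0 * J.T @ r / len(r))))
        history.mu.append(mu)
        if vmse < best_val:
            best_val = vmse
            best = work.copy()
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if history.gradient_norm[-1] < GRADIENT_FLOOR:
            stop = StopReason.GRADIENT_FLOOR
            break
        if epochs_since_best >= patience:
            stop = StopReason.EARLY_STOP
            break
    history.best_epoch = best_epoch
    history.stop_reason = stop
    best.scaler = model.scaler
    return best, history


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

def predict(
    model: MLPModel, features: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities in [0,1], binary labels at the threshold).

    Features must be on the training scale; when the model carries a
    fitted scaler it is applied here.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if model.scaler is not None and model.scaler.data_min is not None:
        X = model.scaler.transform(X)
    prob = model.forward(X)
    return prob, (prob >= threshold).astype(int)


def confusion_and_accuracy(
    labels: Sequence[int], predictions: Sequence[int]
) -> tuple[int, int, int, int, float]:
    """(TN, FP, FN, TP, accuracy) with arrhythmia as the positive class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if len(y) != len(p) or len(y) == 0:
        raise InvalidArgumentError("labels and predictions must have equal length >= 1")
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tp = int(np.sum((y == 1) & (p == 1)))
    return tn, fp, fn, tp, (tn + tp) / len(y)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 42,
    max_epochs: int = 10,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[MLPModel, TrainingHistory, dict]:
    """Split, scale, train and evaluate in one call.

    Returns the trained model (with its scaler attached), the training
    history, and a report dict with per-split accuracies and the confusion
    counts on the whole dataset, mirroring a confusion-matrix summary over
    all examples.
    """
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise SingleClassError(
            "training requires both normal and arrhythmic examples"
        )
    idx_train, idx_val, idx_test = split_dataset(
        list(range(len(y))), fractions=fractions, seed=seed, labels=y
    )
    scaler = MinMaxScaler().fit(np.asarray(X, dtype=float)[idx_train])
    Xs = scaler.transform(X)
    model = init_network(input_dim=Xs.shape[1], seed=seed)
    model.scaler = scaler
    trained, history = train_lm(
        model,
        Xs[idx_train],
        y[idx_train],
        Xs[idx_val],
        y[idx_val],
        max_epochs=max_epochs,
    )
    report = {}
    for name, idx in (
        ("train", idx_train),
        ("val", idx_val),
        ("test", idx_test),
    ):
        _, pred = predict(trained, np.asarray(X, dtype=float)[idx])
        *_, acc = confusion_and_accuracy(y[idx], pred)
        report[f"{name}_accuracy"] = acc
    _, pred_all = predict(trained, np.asarray(X, dtype=float))
    tn, fp, fn, tp, acc = confusion_and_accuracy(y, pred_all)
    report["confusion"] = {"tn": tn, "fp": fp, "fn": fn, "tp": tp}
    report["overall_accuracy"] = acc
    return trained, history, report
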