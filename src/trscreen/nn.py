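"""A 1-D convolutional binary classifier implemented directly in numpy.

Architecture (fixed by :class:`NetworkSpec`, defaults shown):

    input  (L, 1)  standardized expression along a fixed gene axis
    Conv1D  32 filters, kernel 5, no padding, ReLU      f(x) = max(0, x)
    MaxPool 2 (stride 2, floor on odd lengths), Dropout 0.3
    Conv1D  64 filters, kernel 5, no padding, ReLU
    MaxPool 2, Dropout 0.4
    Flatten -> Dense 64, ReLU, Dropout 0.5
    Dense 1, sigmoid                                    f(x) = 1 / (1 + e^-x)

trained with the Adam optimizer on the binary cross-entropy

    loss = -[ y * log p + (1 - y) * log(1 - p) ]

under two callbacks: early stopping on validation loss (restoring the
best-epoch weights) and learning-rate halving on a validation-loss plateau.

The length chain under valid (no-padding) convolution with kernel k = 5 is
L -> L-4 -> floor(L/2) -> -4 -> floor(/2); the input must be long enough
that at least one position survives (L >= 26 for the default kernel/pool).

Everything is float32 and driven by explicit :class:`numpy.random.Generator`
streams (weight init, batch shuffling, dropout), so runs are bit-reproducible
for a given seed on a given BLAS.  Convolutions are evaluated as matrix
products over im2col patch views; with panel-sized inputs (hundreds of
genes) a full training run takes seconds per fold on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError

EPS = 1e-7  # probability clip for the cross-entropy


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Shape of the convolutional screener (defaults are the reference design)."""

    input_length: int
    filters1: int = 32
    filters2: int = 64
    kernel: int = 5
    pool: int = 2
    dropout1: float = 0.3
    dropout2: float = 0.4
    dense_units: int = 64
    dropout_dense: float = 0.5

    def shape_chain(self) -> tuple[int, int, int, int, int]:
        """(L, L-k+1, pool1, conv2, pool2) length chain; raises if it collapses."""
        L = self.input_length
        if self.kernel == 5 and self.pool == 2 and L < 26:
            raise ConfigError(
                f"input_length {L} below the supported minimum of 26 for the "
                f"default kernel-5/pool-2 geometry"
            )
        c1 = L - self.kernel + 1
        p1 = c1 // self.pool
        c2 = p1 - self.kernel + 1
        p2 = c2 // self.pool
        if min(c1, p1, c2, p2) < 1:
            raise ConfigError(
                f"input_length {L} too short: the conv/pool chain "
                f"{L}->{c1}->{p1}->{c2}->{p2} leaves no positions (need >= 26 "
                f"for kernel {self.kernel}, pool {self.pool})"
            )
        return L, c1, p1, c2, p2

    @property
    def flatten_length(self) -> int:
        return self.shape_chain()[4] * self.filters2

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class TrainConfig:
    """Optimization settings for one fold (defaults are the reference recipe)."""

    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    early_stop_patience: int = 10
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 5
    k_folds: int = 5
    split_fraction: float = 0.8
    seed: int = 42

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must lie strictly between 0 and 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ConfigError("callback patiences must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(y_true: np.ndarray, p: np.ndarray) -> float:
    """Mean BCE over samples, probabilities clipped to [EPS, 1-EPS]."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.clip(np.asarray(p, dtype=np.float64).ravel(), EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) patch matrix, kernel-position major."""
    win = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=1)  # (B, P, C, k)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - kernel + 1, kernel * x.shape[2]
    )


def _col_scatter(dpatch: np.ndarray, L: int, C: int, kernel: int) -> np.ndarray:
    """Adjoint of _im2col: (B, P, k*C) -> (B, L, C)."""
    B, P, _ = dpatch.shape
    dp = dpatch.reshape(B, P, kernel, C)
    dx = np.zeros((B, L, C), dtype=dpatch.dtype)
    for k in range(kernel):
        dx[:, k : k + P, :] += dp[:, :, k, :]
    return dx


def _maxpool(x: np.ndarray, pool: int) -> tuple[np.ndarray, np.ndarray]:
    """(B, L, C) -> (B, L//pool, C); also returns argmax for the backward pass.

    Ties go to the earliest position (argmax convention).  pool == 2 takes a
    branch-free fast path; other sizes use the generic argmax.
    """
    B, L, C = x.shape
    P = L // pool
    xt = x[:, : P * pool, :].reshape(B, P, pool, C)
    if pool == 2:
        a, b = xt[:, :, 0, :], xt[:, :, 1, :]
        right = b > a
        return np.where(right, b, a), right.astype(np.int8)
    arg = xt.argmax(axis=2)
    out = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, arg


def _maxpool_backward(dout: np.ndarray, arg: np.ndarray, L: int, pool: int) -> np.ndarray:
    B, P, C = dout.shape
    dx = np.zeros((B, L, C), dtype=dout.dtype)
    if pool == 2:
        sel = arg.astype(bool)
        dx[:, 0 : 2 * P : 2, :] = dout * ~sel
        dx[:, 1 : 2 * P : 2, :] = dout * sel
        return dx
    dxt = np.zeros((B, P, pool, C), dtype=dout.dtype)
    np.put_along_axis(dxt, arg[:, :, None, :].astype(np.intp), dout[:, :, None, :], axis=2)
    dx[:, : P * pool, :] = dxt.reshape(B, P * pool, C)
    return dx


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


class ConvNet1D:
    """The convolutional screener: parameters, forward pass, and gradients."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        L, c1, p1, c2, p2 = spec.shape_chain()
        self.flat = p2 * spec.filters2
        rng = np.random.default_rng(self.seed)
        k = spec.kernel
        self.params: dict[str, np.ndarray] = {
            "W1": _glorot(rng, k * 1, k * spec.filters1, (k * 1, spec.filters1)),
            "b1": np.zeros(spec.filters1, dtype=np.float32),
            "W2": _glorot(rng, k * spec.filters1, k * spec.filters2, (k * spec.filters1, spec.filters2)),
            "b2": np.zeros(spec.filters2, dtype=np.float32),
            "W3": _glorot(rng, self.flat, spec.dense_units, (self.flat, spec.dense_units)),
            "b3": np.zeros(spec.dense_units, dtype=np.float32),
            "W4": _glorot(rng, spec.dense_units, 1, (spec.dense_units, 1)),
            "b4": np.zeros(1, dtype=np.float32),
        }

    # -- weights ----------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in PARAM_NAMES:
            if k not in weights:
                raise ContractError(f"missing parameter {k!r}")
            if weights[k].shape != self.params[k].shape:
                raise ContractError(
                    f"parameter {k!r} shape {weights[k].shape} != expected {self.params[k].shape}"
                )
            self.params[k] = weights[k].astype(np.float32).copy()

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """x (B, L) standardized features -> probabilities (B,), plus cache."""
        spec = self.spec
        P = self.params
        if x.ndim != 2 or x.shape[1] != spec.input_length:
            raise ContractError(f"input shape {x.shape} != (B, {spec.input_length})")
        if training and rng is None:
            raise ContractError("training forward pass needs a dropout rng")
        dtype = P["W1"].dtype  # float32 in production; float64 for gradient checks
        x3 = np.ascontiguousarray(x, dtype=dtype)[:, :, None]
        cache: dict = {}

        cols1 = _im2col(x3, spec.kernel)
        z1 = cols1 @ P["W1"] + P["b1"]
        a1 = relu(z1)
        pool1, arg1 = _maxpool(a1, spec.pool)
        d1 = self._dropout(pool1, spec.dropout1, training, rng, cache, "m1")

        cols2 = _im2col(d1, spec.kernel)
        z2 = cols2 @ P["W2"] + P["b2"]
        a2 = relu(z2)
        pool2, arg2 = _maxpool(a2, spec.pool)
        d2 = self._dropout(pool2, spec.dropout2, training, rng, cache, "m2")

        flat = d2.reshape(x.shape[0], -1)
        z3 = flat @ P["W3"] + P["b3"]
        a3 = relu(z3)
        d3 = self._dropout(a3, spec.dropout_dense, training, rng, cache, "m3")
        z4 = d3 @ P["W4"] + P["b4"]
        prob = sigmoid(z4)[:, 0]

        cache.update(
            x3=x3, cols1=cols1, z1=z1, a1=a1, arg1=arg1, d1=d1,
            cols2=cols2, z2=z2, a2=a2, arg2=arg2, d2=d2,
            flat=flat, z3=z3, d3=d3, prob=prob,
        )
        return prob, cache

    @staticmethod
    def _dropout(x, rate, training, rng, cache, key):
        if not training or rate <= 0.0:
            cache[key] = None
            return x
        mask = (rng.random(x.shape) >= rate).astype(x.dtype) / x.dtype.type(1.0 - rate)
        cache[key] = mask
        return x * mask

    # -- backward ---------------------------------------------------------
    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Mean batch BCE, gradients for every parameter, and the training-mode
        probabilities (used for on-the-fly accuracy tracking)."""
        spec, P = self.spec, self.params
        dtype = P["W1"].dtype
        B = x.shape[0]
        prob, c = self.forward(x, training=True, rng=rng)
        yf = np.asarray(y, dtype=dtype).ravel()
        loss = binary_cross_entropy(yf, prob)

        # sigmoid + clipped BCE collapses to (p - y)/B on the logit; the clip
        # zeroes the gradient for fully saturated outputs
        inside = (prob > EPS) & (prob < 1.0 - EPS)
        dz4 = ((prob - yf) * inside / B).astype(dtype)[:, None]

        grads: dict[str, np.ndarray] = {}
        grads["W4"] = c["d3"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        dd3 = dz4 @ P["W4"].T
        if c["m3"] is not None:
            dd3 = dd3 * c["m3"]
        dz3 = dd3 * (c["z3"] > 0)
        grads["W3"] = c["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ P["W3"].T

        _, c1, p1, c2, p2 = spec.shape_chain()
        dd2 = dflat.reshape(B, p2, spec.filters2)
        if c["m2"] is not None:
            dd2 = dd2 * c["m2"]
        da2 = _maxpool_backward(dd2, c["arg2"], c2, spec.pool)
        dz2 = da2 * (c["z2"] > 0)
        grads["W2"] = np.tensordot(c["cols2"], dz2, axes=([0, 1], [0, 1]))
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ P["W2"].T
        dd1 = _col_scatter(dcols2, p1, spec.filters1, spec.kernel)
        if c["m1"] is not None:
            dd1 = dd1 * c["m1"]
        da1 = _maxpool_backward(dd1, c["arg1"], c1, spec.pool)
        dz1 = da1 * (c["z1"] > 0)
        grads["W1"] = np.tensordot(c["cols1"], dz1, axes=([0, 1], [0, 1]))
        grads["b1"] = dz1.sum(axis=(0, 1))
        return loss, {k: v.astype(dtype) for k, v in grads.items()}, prob

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Inference probabilities (dropout inactive), in sample order."""
        out = np.empty(x.shape[0], dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self.forward(x[start : start + batch_size], training=False)
            out[start : start + probs.shape[0]] = probs
        return out


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(
                np.float32
            )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def train_network(
    net: ConvNet1D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> TrainingHistory:
    """Mini-batch Adam with early stopping and LR-on-plateau; mutates ``net``.

    Monitors validation loss; when it fails to improve for
    ``lr_reduce_patience`` epochs the learning rate is halved, and after
    ``early_stop_patience`` epochs training stops and the best-epoch
    weights are restored.
    """
    config.validate()
    y_train = np.asarray(y_train, dtype=np.float32).ravel()
    y_val = np.asarray(y_val, dtype=np.float32).ravel()
    if len(set(y_train.tolist())) < 2:
        raise ContractError("training fold contains a single class")
    rng = np.random.default_rng(seed)
    shuffle_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))

    opt = Adam(net.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_weights = net.get_weights()
    wait_stop = wait_lr = 0
    n = x_train.shape[0]

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads, prob = net.loss_and_grads(x_train[idx], y_train[idx], dropout_rng)
            opt.step(net.params, grads)
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum((prob >= 0.5) == (y_train[idx] == 1)))
        val_prob = net.predict(x_val)
        val_loss = binary_cross_entropy(y_val, val_prob)
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(float(np.mean((val_prob >= 0.5) == (y_val == 1))))
        history.learning_rate.append(opt.lr)
        history.stopped_epoch = epoch + 1

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = net.get_weights()
            history.best_epoch = epoch + 1
            wait_stop = wait_lr = 0
        else:
            wait_stop += 1
            wait_lr += 1
            if wait_lr >= config.lr_reduce_patience:
                opt.lr *= config.lr_reduce_factor
                wait_lr = 0
            if wait_stop >= config.early_stop_patience:
                break

    net.set_weights(best_weights)
    return history
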