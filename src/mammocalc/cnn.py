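"""Small convolutional binary classifier over the 8-channel feature stack.

Architecture (valid, i.e. unpadded, convolutions; floor-division max pools):

    input (S, S, 8)
    -> [conv k x k, F filters -> ReLU -> maxpool p x p]  per block
    -> flatten -> dense (ReLU, dropout) -> dense 1 -> sigmoid

With the default two blocks of (16 filters, 3x3, pool 2) on a 508 x 508 x 8
input the layer sides are 506 -> 253 -> 251 -> 125 and the flatten length is
125 * 125 * 16 = 250,000.  A third block can be added through ``conv_blocks``.

The network is implemented directly on numpy: im2col convolution, manual
backpropagation, Adam updates, binary cross-entropy with an L2 weight
penalty, and inverted dropout on the dense hidden layer (training only).
Everything is seeded, so two builds or two training runs with the same seed
are bit-identical.  The sigmoid output is thresholded with a strict '>'
(probability exactly at the threshold classifies negative).

Learning-rate note: the default is the tuned value 1e-6 appropriate for
full-scale training; small synthetic experiments use a larger rate passed
explicitly (see TrainConfig).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "PredictionResult",
    "infer_shapes",
    "build_model",
    "train",
    "predict",
    "CNNModel",
    "CNNClassifier",
]


@dataclass
class CNNConfig:
    input_shape: tuple[int, int, int] = (508, 508, 8)
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 3, 2), (16, 3, 2))
    dense_units: int = 64

    def validate(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("at least one conv block is required")
        for f, k, p in self.conv_blocks:
            if k % 2 == 0 or k < 1:
                raise ValueError("kernel side must be odd and positive")
            if p < 1:
                raise ValueError("pool side must be >= 1")
            if f < 1:
                raise ValueError("filter count must be positive")
        if self.dense_units < 1:
            raise ValueError("dense_units must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-6
    batch_size: int = 8
    epochs: int = 80
    dropout: float = 0.2
    l2: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")


@dataclass
class PredictionResult:
    probability: float
    label: int
    threshold: float = 0.5


def infer_shapes(config: CNNConfig) -> tuple[list[tuple[str, int, int, int]], int]:
    """Layer-by-layer output shapes plus the flatten length.

    A valid convolution shrinks each side by kernel_side - 1; a max pool
    divides by the pool side with floor.  Raises if any side collapses.
    """
    config.validate()
    r, c, ch = config.input_shape
    layers: list[tuple[str, int, int, int]] = [("input", r, c, ch)]
    for i, (f, k, p) in enumerate(config.conv_blocks, 1):
        r, c = r - (k - 1), c - (k - 1)
        if r <= 0 or c <= 0:
            raise ValueError(f"conv block {i} collapses the image ({r}x{c})")
        layers.append((f"conv{i}", r, c, f))
        layers.append((f"relu{i}", r, c, f))
        r, c = r // p, c // p
        if r <= 0 or c <= 0:
            raise ValueError(f"pool block {i} collapses the image ({r}x{c})")
        layers.append((f"pool{i}", r, c, f))
        ch = f
    flatten = r * c * ch
    layers.append(("flatten", 1, flatten, 1))
    return layers, flatten


# ---------------------------------------------------------------------------
# numpy layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, H, W, C) -> (n, Ho, Wo, k, k, C) view of kxk patches."""
    v = sliding_window_view(x, (k, k), axis=(1, 2))   # (n, Ho, Wo, C, k, k)
    return np.ascontiguousarray(np.moveaxis(v, 3, -1))  # (n, Ho, Wo, k, k, C)


def _conv_forward(x, W, b, k):
    patches = _im2col(x, k)
    n, Ho, Wo = patches.shape[:3]
    out = patches.reshape(n * Ho * Wo, -1) @ W + b
    F = W.shape[1]
    return out.reshape(n, Ho, Wo, F), patches


def _conv_backward(dout, patches, W, x_shape, k):
    n, Ho, Wo, F = dout.shape
    dmat = dout.reshape(n * Ho * Wo, F)
    pmat = patches.reshape(n * Ho * Wo, -1)
    dW = pmat.T @ dmat
    db = dmat.sum(axis=0)
    dpatches = (dmat @ W.T).reshape(n, Ho, Wo, k, k, -1)
    dx = np.zeros(x_shape)
    for i in range(k):
        for j in range(k):
            dx[:, i:i + Ho, j:j + Wo, :] += dpatches[:, :, :, i, j, :]
    return dx, dW, db


def _pool_forward(x, p):
    n, H, W, C = x.shape
    Ho, Wo = H // p, W // p
    xc = x[:, :Ho * p, :Wo * p, :].reshape(n, Ho, p, Wo, p, C)
    out = xc.max(axis=(2, 4))
    return out, (xc, out)


def _pool_backward(dout, cache, x_shape, p):
    xc, out = cache
    n, Ho, _, Wo, _, C = xc.shape
    mask = xc == out[:, :, None, :, None, :]
    # distribute over ties evenly so the gradient stays a subgradient
    counts = mask.sum(axis=(2, 4), keepdims=True)
    g = mask * (dout[:, :, None, :, None, :] / counts)
    dx = np.zeros(x_shape)
    dx[:, :Ho * p, :Wo * p, :] = g.reshape(n, Ho * p, Wo * p, C)
    return dx


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CNNModel:
    """Parameter container with forward/backward passes and Adam state."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        layers, flatten = infer_shapes(config)
        self.config = config
        self.layers = layers
        self.flatten = flatten
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = config.input_shape[2]
        for i, (f, k, p) in enumerate(config.conv_blocks):
            fan_in = k * k * cin
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, f))
            self.params[f"b{i}"] = np.zeros(f)
            cin = f
        nb = len(config.conv_blocks)
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flatten), (flatten, config.dense_units))
        self.params["bd"] = np.zeros(config.dense_units)
        self.params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / config.dense_units), (config.dense_units, 1))
        self.params["bo"] = np.zeros(1)
        self._n_blocks = nb
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- inference ---------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Probabilities for a batch (n, H, W, C); returns (p, cache)."""
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{tuple(self.config.input_shape)}")
        cache: dict = {"inputs": [], "patches": [], "relu": [], "pool": [],
                       "pre_pool_shape": []}
        h = x
        for i, (f, k, p) in enumerate(self.config.conv_blocks):
            cache["inputs"].append(h)
            z, patches = _conv_forward(h, self.params[f"W{i}"], self.params[f"b{i}"], k)
            cache["patches"].append(patches)
            a = np.maximum(z, 0.0)
            cache["relu"].append(a > 0)
            cache["pre_pool_shape"].append(a.shape)
            h, pc = _pool_forward(a, p)
            cache["pool"].append(pc)
        n = h.shape[0]
        flat = h.reshape(n, -1)
        cache["flat_in_shape"] = h.shape
        cache["flat"] = flat
        zd = flat @ self.params["Wd"] + self.params["bd"]
        ad = np.maximum(zd, 0.0)
        cache["relu_d"] = zd > 0
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            mask = (rng.random(ad.shape) >= dropout) / (1.0 - dropout)
            ad = ad * mask
            cache["drop_mask"] = mask
        else:
            cache["drop_mask"] = None
        cache["ad"] = ad
        zo = ad @ self.params["Wo"] + self.params["bo"]
        prob = _sigmoid(zo)[:, 0]
        return prob, cache

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, x, y, l2: float = 0.0, dropout: float = 0.0,
                       rng: np.random.Generator | None = None):
        y = np.asarray(y, dtype=np.float64)
        prob, cache = self.forward(x, dropout=dropout, rng=rng)
        n = prob.shape[0]
        eps = 1e-12
        data_loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        weight_keys = [k for k in self.params if k.startswith("W")]
        reg = 0.5 * l2 * sum(float(np.sum(self.params[k] ** 2)) for k in weight_keys)
        loss = data_loss + reg
        grads: dict[str, np.ndarray] = {}

        dz = ((prob - y) / n)[:, None]                 # d loss / d zo
        grads["Wo"] = cache["ad"].T @ dz
        grads["bo"] = dz.sum(axis=0)
        dad = dz @ self.params["Wo"].T
        if cache["drop_mask"] is not None:
            dad = dad * cache["drop_mask"]
        dzd = dad * cache["relu_d"]
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        dh = dflat.reshape(cache["flat_in_shape"])
        for i in reversed(range(self._n_blocks)):
            f, k, p = self.config.conv_blocks[i]
            da = _pool_backward(dh, cache["pool"][i], cache["pre_pool_shape"][i], p)
            dzc = da * cache["relu"][i]
            dh, dW, db = _conv_backward(dzc, cache["patches"][i], self.params[f"W{i}"],
                                        cache["inputs"][i].shape, k)
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        if l2 > 0:
            for k_ in weight_keys:
                grads[k_] = grads[k_] + l2 * self.params[k_]
        return loss, data_loss, prob, grads

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def state_dict(self) -> dict:
        return copy.deepcopy(self.params)

    def load_state_dict(self, state: dict) -> None:
        self.params = copy.deepcopy(state)


def build_model(config: CNNConfig | None = None, seed: int = 0) -> CNNModel:
    """Seeded model construction; same seed gives identical parameters."""
    return CNNModel(config or CNNConfig(), seed=seed)


def train(model: CNNModel, X_train, y_train, X_val=None, y_val=None,
          tcfg: TrainConfig | None = None, verbose: bool = False) -> pd.DataFrame:
    """Adam / binary-cross-entropy training loop.

    Returns a per-epoch history DataFrame (train/val loss and accuracy).
    The parameters at the best validation loss are restored at the end when
    a validation set is supplied.  Raises on a single-class training set and
    aborts on non-finite loss.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(tcfg.seed)
    n = X_train.shape[0]
    rows = []
    best_val = np.inf
    best_state = None
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for s in range(0, n, tcfg.batch_size):
            idx = order[s:s + tcfg.batch_size]
            loss, data_loss, prob, grads = model.loss_and_grads(
                X_train[idx], y_train[idx], l2=tcfg.l2,
                dropout=tcfg.dropout, rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {s}")
            model.adam_step(grads, tcfg.learning_rate)
            losses.append(loss)
            accs.append(np.mean((prob > 0.5) == y_train[idx]))
        row = {"epoch": epoch,
               "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs)),
               "val_loss": np.nan, "val_acc": np.nan}
        if X_val is not None and len(X_val):
            vprob, _ = model.forward(np.asarray(X_val, dtype=np.float64))
            yv = np.asarray(y_val, dtype=np.float64)
            eps = 1e-12
            vloss = float(-np.mean(yv * np.log(vprob + eps)
                                   + (1 - yv) * np.log(1 - vprob + eps)))
            row["val_loss"] = vloss
            row["val_acc"] = float(np.mean((vprob > 0.5) == yv))
            if vloss < best_val:
                best_val = vloss
                best_state = model.state_dict()
        rows.append(row)
        if verbose:
            print(f"epoch {epoch}: {row}")
    if best_state is not None:
        model.load_state_dict(best_state)
    return pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss",
                                       "train_acc", "val_acc"])


def predict(model: CNNModel, stack, threshold: float = 0.5) -> PredictionResult:
    """Deterministic forward pass (dropout off) on one stack."""
    arr = np.asarray(stack, dtype=np.float64)
    prob, _ = model.forward(arr if arr.ndim == 4 else arr[None])
    p = float(prob[0])
    return PredictionResult(probability=p, label=int(p > threshold),
                            threshold=threshold)


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator around the numpy CNN.

    ``X`` is an array of feature stacks with shape (n, side, side, channels).
    The decision rule is strict: probability > ``threshold``.
    """

    def __init__(self, conv_blocks=((16, 3, 2), (16, 3, 2)), dense_units=64,
                 learning_rate=1e-6, batch_size=8, epochs=80, dropout=0.2,
                 l2=0.01, threshold=0.5, random_state=0):
        self.conv_blocks = conv_blocks
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.l2 = l2
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError("X must have shape (n, side, side, channels)")
        self.classes_ = np.unique(y)
        cfg = CNNConfig(input_shape=tuple(X.shape[1:]),
                        conv_blocks=tuple(tuple(b) for b in self.conv_blocks),
                        dense_units=self.dense_units)
        self.model_ = build_model(cfg, seed=self.random_state)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size, epochs=self.epochs,
                           dropout=self.dropout, l2=self.l2,
                           seed=self.random_state)
        self.history_ = train(self.model_, X, y.astype(float), X_val, y_val, tcfg)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        prob, _ = self.model_.forward(X)
        return np.column_stack([1.0 - prob, prob])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(int)
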