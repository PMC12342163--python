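"""Minimal seeded NumPy neural-network core for the two classifier variants.

Implements exactly what the classifiers need — 1D valid convolution, ReLU,
max pooling, dense layers, softmax cross-entropy, Adam and SGD — with
deterministic initialization and shuffling from a single Generator. No GPU,
no autograd framework; the backward passes are hand-written.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding 1D convolution. Input (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel_size
        fan_in = c_in * kernel_size
        fan_out = c_out * kernel_size
        bound = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        w = rng.uniform(-bound, bound, size=(kernel_size * c_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.c_in = c_in
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, c = x.shape
        self._in_len = length
        # (N, L', k, C) -> (N*L', k*C)
        win = sliding_window_view(x, self.k, axis=1)  # (N, L', C, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, -1, self.k * c)
        if train:
            self._cols = cols
        w, b = self.params
        return cols @ w + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        cols = self._cols
        assert cols is not None
        n, lp, _ = dout.shape
        self.grads[0][...] = np.tensordot(cols, dout, axes=([0, 1], [0, 1]))
        self.grads[1][...] = dout.sum(axis=(0, 1))
        dcols = (dout @ w.T).reshape(n, lp, self.k, self.c_in)
        dx = np.zeros((n, self._in_len, self.c_in))
        for i in range(self.k):
            dx[:, i : i + lp, :] += dcols[:, :, i, :]
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; remainder dropped."""

    def __init__(self, pool_size: int):
        super().__init__()
        self.p = pool_size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, c = x.shape
        lp = length // self.p
        blocks = x[:, : lp * self.p, :].reshape(n, lp, self.p, c)
        self._argmax = blocks.argmax(axis=2)
        self._shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, lp, c = dout.shape
        dblocks = np.zeros((n, lp, self.p, c))
        ni, li, ci = np.ogrid[:n, :lp, :c]
        dblocks[ni, li, self._argmax, ci] = dout
        dx = np.zeros(self._shape)
        dx[:, : lp * self.p, :] = dblocks.reshape(n, lp * self.p, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-bound, bound, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float((onehot * np.log(p + eps)).sum() / n)
    grad = (p - onehot) / n
    return loss, grad


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} weight arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


def make_optimizer(name: str, params: list[np.ndarray], lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


def stratified_validation_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices for a stratified (train, validation) split; every class keeps
    at least one training member, classes of size 1 contribute nothing to
    validation."""
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(y):
        members = np.where(y == cls)[0]
        members = members[rng.permutation(len(members))]
        n_val = int(np.floor(len(members) * fraction + 0.5))
        n_val = min(n_val, len(members) - 1)
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(np.asarray(train_idx, dtype=np.intp)), np.sort(
        np.asarray(val_idx, dtype=np.intp)
    )


def fit_network(
    net: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    *,
    epochs: int,
    batch_size: int,
    optimizer: str,
    learning_rate: float,
    validation_fraction: float,
    patience: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Train with mini-batch cross-entropy; early stopping on a stratified
    validation split restores the best weights. Returns the per-epoch log."""
    onehot = np.eye(n_classes)[y]
    if validation_fraction > 0 and len(y) >= 10:
        tr, va = stratified_validation_split(y, validation_fraction, rng)
    else:
        tr, va = np.arange(len(y)), np.asarray([], dtype=np.intp)
    opt = make_optimizer(optimizer, net.params, learning_rate)
    log: list[dict] = []
    best_val = np.inf
    best_weights = net.get_weights()
    stall = 0
    for epoch in range(epochs):
        order = tr[rng.permutation(len(tr))]
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch + 1} "
                    f"(learning rate {learning_rate}, batch {start // batch_size})"
                )
            net.backward(dlogits)
            opt.step(net.grads)
            epoch_loss += loss * len(idx)
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        entry = {
            "epoch": epoch + 1,
            "train_loss": epoch_loss / len(order),
            "train_accuracy": n_correct / len(order),
        }
        if len(va):
            vlogits = net.forward(x[va], train=False)
            vloss, _ = softmax_cross_entropy(vlogits, onehot[va])
            entry["val_loss"] = vloss
            entry["val_accuracy"] = float((vlogits.argmax(axis=1) == y[va]).mean())
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = net.get_weights()
                stall = 0
            else:
                stall += 1
        log.append(entry)
        if len(va) and stall >= patience:
            break
    if len(va):
        net.set_weights(best_weights)
    return log
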