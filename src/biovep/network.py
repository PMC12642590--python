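"""A small, fully seeded feed-forward network stack on NumPy.

Implements exactly the layer vocabulary the variant-effect regressors
need — dense, 1-D convolution over residue positions, spectral graph
convolution over a fixed contact graph, leaky ReLU, inverted dropout —
plus Adam and an early-stopping mean-squared-error training loop.
Everything is deterministic given the seeds supplied by the caller:
weight initialization, batch order, and dropout masks all draw from
explicit generators.

Array convention: structured inputs are ``(batch, L, channels)``;
``Flatten`` produces ``(batch, L * channels)`` for the dense head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEAKY_SLOPE = 0.2


class Layer:
    """Base layer: forward caches what backward needs; params/grads align."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = LEAKY_SLOPE):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Conv1D(Layer):
    """Valid-padding, stride-1 convolution along the residue axis.

    Input ``(B, L, C)`` -> output ``(B, L - k + 1, F)``; implemented as an
    im2col matrix product.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.in_channels = in_channels
        fan_in = kernel * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        k = self.kernel
        if L < k:
            raise ValueError(f"sequence length {L} shorter than kernel {k}")
        # (B, L_out, C, k) -> (B, L_out, k, C) so the flat order is (offset, channel)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = win.transpose(0, 1, 3, 2).reshape(B, L - k + 1, k * C)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, grad):
        B, L_out, F = grad.shape
        k, C = self.kernel, self.in_channels
        self.grads[0][...] = self._cols.reshape(-1, k * C).T @ grad.reshape(-1, F)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dcols = (grad @ self.W.T).reshape(B, L_out, k, C)
        dx = np.zeros(self._in_shape)
        for j in range(k):
            dx[:, j : j + L_out, :] += dcols[:, :, j, :]
        return dx


class GraphConv(Layer):
    """Spectral graph convolution ``Y = A_hat X W + b`` with fixed ``A_hat``.

    ``A_hat`` is the symmetric-normalized adjacency with self-loops; on an
    edgeless graph it is the identity, so the layer degenerates to a shared
    per-node dense map.
    """

    def __init__(self, a_hat: np.ndarray, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.a_hat = np.asarray(a_hat, dtype=float)
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_channels), size=(in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        if x.shape[1] != self.a_hat.shape[0]:
            raise ValueError(
                f"graph has {self.a_hat.shape[0]} nodes but input has {x.shape[1]} rows"
            )
        self._xa = np.matmul(self.a_hat, x)  # broadcasts over the batch
        return self._xa @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = np.tensordot(self._xa, grad, axes=([0, 1], [0, 1]))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dxa = grad @ self.W.T
        return np.matmul(self.a_hat.T, dxa)


class MeanPool(Layer):
    """Global average pooling over the residue axis: (B, L, C) -> (B, C).

    A position-invariant readout: the prediction depends on residue-local
    features only through their average, so weights trained at one set of
    positions apply unchanged at positions never mutated in training.
    """

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad):
        B, L, C = self._shape
        return np.broadcast_to(grad[:, None, :], self._shape) / L


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an explicit generator")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """A layer pipeline with MSE loss on a scalar output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x[:, 0]

    def backward(self, dloss: np.ndarray) -> None:
        grad = dloss[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(out) if out else np.empty(0)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def fit_network(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    epochs: int = 300,
    patience: int = 30,
    lr_decay: float = 0.5,
    lr_patience: int | None = None,
    min_lr: float = 1e-5,
    seed: int = 0,
) -> TrainingHistory:
    """Minimize MSE with Adam, early-stopping on validation loss.

    If ``lr_patience`` is set, the learning rate is multiplied by
    ``lr_decay`` whenever the validation loss fails to improve for that
    many epochs (down to ``min_lr``); off by default, since a small
    validation set under distribution shift makes plateau detection noisy.
    The best-validation weights are restored before returning.  Raises on a
    non-finite loss (usually a learning-rate problem) with the offending
    epoch in the message.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=learning_rate)
    history = TrainingHistory()
    best_state = net.get_state()
    best_val = np.inf
    since_best = 0
    since_decay = 0
    n = len(X_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X_train[idx], y_train[idx]
            pred = net.forward(xb, train=True, rng=rng)
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; reduce the learning rate"
                )
            epoch_loss += loss * len(idx)
            net.backward(2.0 * resid / len(idx))
            opt.step(net.grads)
        history.train_loss.append(epoch_loss / n)
        val_pred = net.predict(X_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history.val_loss.append(val_loss)
        materially_improved = val_loss < best_val - 1e-9
        if val_loss < best_val:  # keep even hair-thin improvements
            best_val = val_loss
            best_state = net.get_state()
            history.best_epoch = epoch
        if materially_improved:
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
            if since_best >= patience:
                history.stopped_early = True
                break
            if lr_patience is not None and since_decay >= lr_patience and opt.lr > min_lr:
                opt.lr = max(opt.lr * lr_decay, min_lr)
                since_decay = 0
    net.set_state(best_state)
    return history
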