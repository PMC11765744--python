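"""Training backends for candidate architectures.

The architecture engine in :mod:`zoocnn.arch` is purely analytic; actually
fitting a candidate requires a trainer backend.  Two are provided:

* ``"numpy"`` — a compact, fully seeded NumPy implementation of the forward
  and backward pass (im2col convolution, ReLU, 2x2 max pooling, dense
  layers, inverted dropout, softmax cross-entropy, Adam).  Single-threaded
  and deterministic; intended for desk-scale problems (small images, tens of
  filters), where each candidate trains in seconds.
* any other name raises :class:`BackendUnavailableError`, directing callers
  to the deterministic surrogate evaluator instead.

Early stopping monitors validation loss with a configurable patience and the
reported metrics are those of the best epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import ArchitectureSpec, count_parameters
from .data import LabeledImageSet
from .metrics import cross_entropy_loss
from .space import HyperConfig

__all__ = [
    "TrainerConfig",
    "EvalResult",
    "BackendUnavailableError",
    "train_and_evaluate",
]


class BackendUnavailableError(RuntimeError):
    """Requested trainer backend is not available in this installation."""


@dataclass(frozen=True)
class TrainerConfig:
    backend: str = "numpy"
    epochs: int = 10
    batch_size: int = 32
    patience: int = 5
    seed: int = 0


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    validation_loss: float
    epochs_run: int


# ---------------------------------------------------------------------------
# NumPy layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, K: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*OH*OW, C*K*K) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (K, K), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, OH, OW, K, K)
    n, c, oh, ow, _, _ = windows.shape
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * K * K)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(dcols, x_shape, K, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, K, K).transpose(0, 3, 1, 2, 4, 5)
    for i in range(K):
        for j in range(K):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class _Conv:
    def __init__(self, c_in: int, nf: int, K: int, stride: int, padding: str, rng):
        scale = np.sqrt(2.0 / (c_in * K * K))  # He initialization
        self.W = (scale * rng.standard_normal((nf, c_in * K * K))).astype(np.float32)
        self.b = np.zeros(nf, dtype=np.float32)
        self.K, self.stride = K, stride
        self.pad = (K - 1) // 2 if padding == "same" else 0
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self.x_shape = x.shape
        cols, (oh, ow) = _im2col(x, self.K, self.stride, self.pad)
        self.cols, self.oh, self.ow = cols, oh, ow
        out = cols @ self.W.T + self.b
        n = x.shape[0]
        pre = out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        self.mask = pre > 0  # fused ReLU
        return pre * self.mask

    def backward(self, dout):
        dout = dout * self.mask
        n, nf, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, nf)
        self.grads = [dmat.T @ self.cols, dmat.sum(axis=0)]
        dcols = dmat @ self.W
        return _col2im(
            dcols, self.x_shape, self.K, self.stride, self.pad, self.oh, self.ow
        )


class _MaxPool:
    def __init__(self, window: int):
        self.w = window
        self.params = []

    def forward(self, x, train):
        w = self.w
        n, c, h, wd = x.shape
        oh, ow = h // w, wd // w
        self.in_shape = x.shape
        xc = x[:, :, : oh * w, : ow * w].reshape(n, c, oh, w, ow, w)
        out = xc.max(axis=(3, 5))
        mask = xc == out[:, :, :, None, :, None]
        self.mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self.oh, self.ow = oh, ow
        return out

    def backward(self, dout):
        w = self.w
        n, c, h, wd = self.in_shape
        d = self.mask * dout[:, :, :, None, :, None]
        dx = np.zeros(self.in_shape, dtype=dout.dtype)
        dx[:, :, : self.oh * w, : self.ow * w] = d.reshape(
            n, c, self.oh * w, self.ow * w
        )
        return dx


class _Flatten:
    params = []

    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, relu: bool, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (scale * rng.standard_normal((n_in, n_out))).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self.x = x
        out = x @ self.W + self.b
        if self.relu:
            self.mask = out > 0
            out = out * self.mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self.mask
        self.grads = [self.x.T @ dout, dout.sum(axis=0)]
        return dout @ self.W.T


class _Dropout:
    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng
        self.params = []

    def forward(self, x, train):
        if not train:
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep) / keep
        return x * self.mask.astype(np.float32)

    def backward(self, dout):
        return dout * self.mask


class _NumpyNet:
    """Network assembled from an ArchitectureSpec (channels-first)."""

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator):
        table = count_parameters(arch)  # also validates + provides shapes
        self.layers = []
        shape = tuple(arch.input_shape)
        n_dense_seen = 0
        dense_total = sum(1 for l in arch.layers if l.kind == "dense")
        for layer, row in zip(arch.layers, table.rows):
            if layer.kind == "conv":
                self.layers.append(
                    _Conv(shape[2], layer.filters, layer.kernel, layer.stride,
                          layer.padding, rng)
                )
            elif layer.kind == "maxpool":
                self.layers.append(_MaxPool(layer.window))
            elif layer.kind == "flatten":
                self.layers.append(_Flatten())
            elif layer.kind == "dense":
                n_dense_seen += 1
                relu = n_dense_seen < dense_total  # terminal dense is linear
                self.layers.append(_Dense(shape[0], layer.units, relu, rng))
            elif layer.kind == "dropout":
                self.layers.append(_Dropout(layer.rate, rng))
            shape = row["Output Shape"]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def probabilities(self, x):
        logits = self.forward(x, train=False).astype(np.float64)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1**self.t
        corr2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _as_nchw(dataset: LabeledImageSet) -> np.ndarray:
    return dataset.images[:, None, :, :].astype(np.float32)


def train_and_evaluate(
    arch: ArchitectureSpec,
    config: HyperConfig,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    trainer: TrainerConfig = TrainerConfig(),
) -> EvalResult:
    """Train an architecture with cross-entropy and report validation metrics.

    Uses the configuration's learning rate; dropout rates live in the
    architecture itself.  Early stopping watches validation loss with
    ``trainer.patience``; the returned accuracy/loss belong to the best
    epoch.  Fully deterministic for a fixed ``trainer.seed``.
    """
    if trainer.backend != "numpy":
        raise BackendUnavailableError(
            f"trainer backend {trainer.backend!r} is not available; use "
            "backend='numpy' or the deterministic surrogate evaluator"
        )
    rng = np.random.default_rng(trainer.seed)
    net = _NumpyNet(arch, rng)
    x_train, y_train = _as_nchw(train_set), np.asarray(train_set.labels)
    x_val, y_val = _as_nchw(val_set), np.asarray(val_set.labels)
    n_classes = int(
        max(y_train.max(initial=0), y_val.max(initial=0))
    ) + 1

    if trainer.epochs == 0:
        probs = net.probabilities(x_val)
        loss = cross_entropy_loss(probs, y_val)
        acc = float(np.mean(probs.argmax(axis=1) == y_val))
        return EvalResult(acc, loss, 0)

    opt = _Adam(net.layers, lr=config.learning_rate)
    best_loss, best_acc, best_epoch = np.inf, 0.0, 0
    stale = 0
    n = len(y_train)
    for epoch in range(1, trainer.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, trainer.batch_size):
            idx = order[start : start + trainer.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = net.forward(xb, train=True).astype(np.float64)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            onehot = np.eye(n_classes)[yb]
            dlogits = ((p - onehot) / len(yb)).astype(np.float32)
            net.backward(dlogits)
            opt.step()
        probs = net.probabilities(x_val)
        val_loss = cross_entropy_loss(probs, y_val)
        val_acc = float(np.mean(probs.argmax(axis=1) == y_val))
        if val_loss < best_loss - 1e-9:
            best_loss, best_acc, best_epoch = val_loss, val_acc, epoch
            stale = 0
        else:
            stale += 1
            if stale >= trainer.patience:
                return EvalResult(best_acc, float(best_loss), epoch)
    return EvalResult(best_acc, float(best_loss), trainer.epochs)


def predict(
    arch: ArchitectureSpec,
    config: HyperConfig,
    train_set: LabeledImageSet,
    eval_set: LabeledImageSet,
    trainer: TrainerConfig = TrainerConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Train on ``train_set`` and return (probabilities, predictions) on
    ``eval_set`` from the final model state."""
    if trainer.backend != "numpy":
        raise BackendUnavailableError(
            f"trainer backend {trainer.backend!r} is not available"
        )
    rng = np.random.default_rng(trainer.seed)
    net = _NumpyNet(arch, rng)
    x_train, y_train = _as_nchw(train_set), np.asarray(train_set.labels)
    n_classes = int(y_train.max(initial=0)) + 1
    opt = _Adam(net.layers, lr=config.learning_rate)
    n = len(y_train)
    for _ in range(trainer.epochs):
        order = rng.permutation(n)
        for start in range(0, n, trainer.batch_size):
            idx = order[start : start + trainer.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = net.forward(xb, train=True).astype(np.float64)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            onehot = np.eye(n_classes)[yb]
            net.backward(((p - onehot) / len(yb)).astype(np.float32))
            opt.step()
    probs = net.probabilities(_as_nchw(eval_set))
    return probs, probs.argmax(axis=1)
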