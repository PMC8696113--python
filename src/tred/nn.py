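"""A small, deterministic 1D convolutional network engine in NumPy.

Implements exactly what the trajectory classifier needs — 1D convolution
(im2col + BLAS matmul), batch normalization, ReLU, max/global-average
pooling, inverted dropout, a linear head, softmax cross-entropy, and SGD
with momentum and L2 weight decay — with hand-derived backward passes.
Everything is float32 and driven by explicit ``numpy.random.Generator``
instances, so training is bit-reproducible for a given seed on a given
BLAS build.

The only network defined here is :class:`ResNet14`, the 14-weight-layer
1D residual network used for trajectory classification: one stem
convolution, six residual blocks of two convolutions each, and one fully
connected output head.  Projection shortcuts (1×1 convolutions at stage
entries) follow the usual ResNet convention of not counting toward the
depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: parameters, gradients, and a forward/backward pair."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def decay_keys(self) -> set[str]:
        """Parameter names subject to L2 weight decay."""
        return set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution without bias (a batch norm always follows)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.dW = np.zeros_like(self.W)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def params(self):
        return {"W": self.W}

    def grads(self):
        return {"W": self.dW}

    def decay_keys(self):
        return {"W"}

    def forward(self, x, train):
        n, c, l = x.shape
        self._in_len = l
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        # (n, c_in, l_out, k) -> (n, l_out, c_in * k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n, win.shape[2], c * self.kernel
        )
        self._cols = cols if train else None
        y = cols @ self.W.T  # (n, l_out, c_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        assert self._cols is not None, "backward before training forward"
        n, _, l_out = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (n, l_out, c_out)
        flat_dy = dyt.reshape(-1, self.c_out)
        self.dW[...] = flat_dy.T @ self._cols.reshape(-1, self.c_in * self.kernel)
        dcols = (dyt @ self.W).reshape(n, l_out, self.c_in, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c_in, l_out, k)
        lp = self._in_len + 2 * self.pad
        dxp = np.zeros((n, self.c_in, lp), dtype=F32)
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * l_out : self.stride] += dcols[:, :, :, j]
        self._cols = None
        return dxp[:, :, self.pad : self.pad + self._in_len] if self.pad else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = np.sum(dy * xhat, axis=(0, 2))
        self.dbeta[...] = np.sum(dy, axis=(0, 2))
        g = self.gamma[None, :, None] * inv_std[None, :, None]
        mean_dy = np.mean(dy, axis=(0, 2))[None, :, None]
        mean_dy_xhat = np.mean(dy * xhat, axis=(0, 2))[None, :, None]
        return (g * (dy - mean_dy - xhat * mean_dy_xhat)).astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2

    def forward(self, x, train):
        self._in_len = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        idx = np.argmax(win, axis=3)
        if train:
            self._idx, self._shape = idx, xp.shape
        return np.take_along_axis(win, idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        dxp = np.zeros(self._shape, dtype=F32)
        l_out = dy.shape[2]
        for j in range(self.kernel):
            mask = self._idx == j
            dxp[:, :, j : j + self.stride * l_out : self.stride] += dy * mask
        return dxp[:, :, self.pad : self.pad + self._in_len] if self.pad else dxp


class GlobalAvgPool(Layer):
    """Mean over the time axis: (n, c, l) -> (n, c)."""

    def forward(self, x, train):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._l, self._l, axis=2).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)).astype(F32)
        self.b = np.zeros(d_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def decay_keys(self):
        return {"W"}

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus a (possibly projected) shortcut, then ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj: Conv1d | None = Conv1d(c_in, c_out, 1, stride, rng)
            self.proj_bn: BatchNorm1d | None = BatchNorm1d(c_out)
        else:
            self.proj = self.proj_bn = None

    @property
    def sublayers(self) -> list[Layer]:
        layers = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            layers += [self.proj, self.proj_bn]
        return layers

    def params(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.sublayers)
                for k, v in l.params().items()}

    def grads(self):
        return {f"{i}.{k}": v for i, l in enumerate(self.sublayers)
                for k, v in l.grads().items()}

    def decay_keys(self):
        return {f"{i}.{k}" for i, l in enumerate(self.sublayers) for k in l.decay_keys()}

    def forward(self, x, train):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        return self.relu_out.forward(out + shortcut, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        d_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        if self.proj is not None:
            d_short = self.proj.backward(self.proj_bn.backward(d))
        else:
            d_short = d
        return d_main + d_short


class ResNet14:
    """14-weight-layer 1D residual network for multichannel time series.

    Layout: stem convolution (kernel 7, stride 2) + max pool, then three
    stages of two residual blocks each with channel widths
    ``base_channels × (1, 2, 4)`` and stride-2 downsampling at stage
    entry, global average pooling over time, dropout, and a linear
    softmax head.  Weight-bearing layers on the main path:
    1 (stem) + 6 blocks × 2 convolutions + 1 (head) = 14.
    """

    MIN_INPUT_LEN = 16  # net downsampling factor (stem 2 × pool 2 × stages 2·2)

    def __init__(self, n_channels: int, n_classes: int, base_channels: int = 64,
                 dropout_rate: float = 0.4, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        c = base_channels
        self.stem = Conv1d(n_channels, c, kernel=7, stride=2, rng=rng)
        self.stem_bn = BatchNorm1d(c)
        self.stem_relu = ReLU()
        self.pool = MaxPool1d(3, 2)
        self.blocks = [
            ResidualBlock(c, c, 1, rng),
            ResidualBlock(c, c, 1, rng),
            ResidualBlock(c, 2 * c, 2, rng),
            ResidualBlock(2 * c, 2 * c, 1, rng),
            ResidualBlock(2 * c, 4 * c, 2, rng),
            ResidualBlock(4 * c, 4 * c, 1, rng),
        ]
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(dropout_rate, self.dropout_rng)
        self.head = Linear(4 * c, n_classes, rng)
        self.n_channels, self.n_classes = n_channels, n_classes
        self.base_channels, self.dropout_rate = base_channels, dropout_rate
        self.feature_dim = 4 * c

    # -- introspection ------------------------------------------------------
    @property
    def weight_layer_count(self) -> int:
        """Main-path weight-bearing layers (stem + block convs + head)."""
        return 1 + sum(2 for _ in self.blocks) + 1

    @property
    def projection_layer_count(self) -> int:
        """Shortcut 1×1 convolutions (not counted toward network depth)."""
        return sum(1 for b in self.blocks if b.proj is not None)

    def _layers(self) -> list[tuple[str, Layer]]:
        named: list[tuple[str, Layer]] = [("stem", self.stem), ("stem_bn", self.stem_bn)]
        named += [(f"block{i}", b) for i, b in enumerate(self.blocks)]
        named.append(("head", self.head))
        return named

    def params(self) -> dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, l in self._layers() for k, v in l.params().items()}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, l in self._layers() for k, v in l.grads().items()}

    def decay_keys(self) -> set[str]:
        return {f"{n}.{k}" for n, l in self._layers() for k in l.decay_keys()}

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params().items()}
        # running statistics of every batch norm
        for name, bn in self._batchnorms():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params().items():
            v[...] = state[k]
        for name, bn in self._batchnorms():
            bn.running_mean[...] = state[f"{name}.running_mean"]
            bn.running_var[...] = state[f"{name}.running_var"]

    def _batchnorms(self) -> list[tuple[str, BatchNorm1d]]:
        out: list[tuple[str, BatchNorm1d]] = [("stem_bn", self.stem_bn)]
        for i, b in enumerate(self.blocks):
            out.append((f"block{i}.bn1", b.bn1))
            out.append((f"block{i}.bn2", b.bn2))
            if b.proj_bn is not None:
                out.append((f"block{i}.proj_bn", b.proj_bn))
        return out

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                return_features: bool = False):
        """Logits (and optionally the pooled penultimate features)."""
        if x.ndim != 3 or x.shape[1] != self.n_channels:
            raise ValueError(
                f"expected input (n, {self.n_channels}, length), got {x.shape}"
            )
        if x.shape[2] < self.MIN_INPUT_LEN:
            raise ValueError(
                f"input length {x.shape[2]} < minimum receptive length "
                f"{self.MIN_INPUT_LEN}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")
        h = x.astype(F32, copy=False)
        h = self.pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(h, train), train), train),
            train,
        )
        for b in self.blocks:
            h = b.forward(h, train)
        feats = self.gap.forward(h, train)
        logits = self.head.forward(self.dropout.forward(feats, train), train)
        return (logits, feats) if return_features else logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dropout.backward(self.head.backward(dlogits))
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.pool.backward(d)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(d)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(F32)


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay.

    Decay applies only to convolution and linear weights, not to batch-norm
    parameters or biases.
    """

    def __init__(self, net: ResNet14, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = {k: np.zeros_like(v) for k, v in net.params().items()}
        self._decay = net.decay_keys()

    def step(self) -> None:
        params, grads = self.net.params(), self.net.grads()
        for k, w in params.items():
            g = grads[k]
            if self.weight_decay and k in self._decay:
                g = g + self.weight_decay * w
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * g
            w += v


@dataclass
class TrainingHistory:
    """Per-epoch losses and accuracies, plus the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def fit_network(
    net: ResNet14,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 5e-4,
    momentum: float = 0.9,
    weight_decay: float = 5e-4,
    batch_size: int = 32,
    max_epochs: int = 100,
    patience: int = 10,
    seed: int = 0,
) -> TrainingHistory:
    """Train with SGD + momentum, early-stopping on validation loss.

    The network is left holding the weights of the best validation epoch.
    Batch order is drawn from ``seed``; with identical inputs and seed the
    run is reproducible.
    """
    rng = np.random.default_rng(seed)
    opt = SGD(net, lr=lr, momentum=momentum, weight_decay=weight_decay)
    hist = TrainingHistory()
    best_val = np.inf
    best_state = net.state_dict()
    since_best = 0
    n = len(X_train)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(X_train[idx], train=True)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int(np.sum(np.argmax(logits, axis=1) == y_train[idx]))
        hist.train_loss.append(float(np.sum(losses) / n))
        hist.train_acc.append(correct / n)

        val_logits = predict_logits(net, X_val, batch_size=max(batch_size, 64))
        val_loss, _ = cross_entropy(val_logits, y_val)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(float(np.mean(np.argmax(val_logits, axis=1) == y_val)))

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.state_dict()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                hist.stopped_early = True
                break
    net.load_state_dict(best_state)
    return hist


def predict_logits(net: ResNet14, X: np.ndarray, batch_size: int = 64,
                   return_features: bool = False):
    """Inference forward pass in batches (batching does not affect outputs)."""
    logits_parts, feat_parts = [], []
    for start in range(0, len(X), batch_size):
        out = net.forward(X[start : start + batch_size], train=False,
                          return_features=return_features)
        if return_features:
            logits_parts.append(out[0])
            feat_parts.append(out[1])
        else:
            logits_parts.append(out)
    logits = np.concatenate(logits_parts)
    if return_features:
        return logits, np.concatenate(feat_parts)
    return logits
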