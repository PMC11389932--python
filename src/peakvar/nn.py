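"""Minimal 1-D convolutional network engine on numpy.

Implements exactly the layer vocabulary the accessibility models need —
1-D convolution (stride-able), ReLU, max pooling, inverted dropout, dense
layers — together with SGD (optional momentum, constant or triangular cyclic
learning rate), MSE / threshold-weighted MSE / cross-entropy losses and
reverse-mode gradients. Deterministic given a seed: all randomness (weight
init, shuffling, dropout masks) flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    # (array, grad_array, l2) triples; default: no parameters
    def params(self):
        return []


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (N, L, C) inputs."""

    def __init__(self, in_channels, n_filters, kernel, stride=1, l2=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * in_channels))  # He init for ReLU stacks
        self.W = (rng.standard_normal((kernel * in_channels, n_filters)) * scale).astype(
            np.float64
        )
        self.b = np.zeros(n_filters)
        self.kernel = kernel
        self.stride = stride
        self.in_channels = in_channels
        self.l2 = l2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_length(self, L):
        if L < self.kernel:
            raise ValueError(
                f"input length {L} shorter than kernel {self.kernel}"
            )
        return (L - self.kernel) // self.stride + 1

    def _cols(self, x):
        # (N, L-k+1, C, k) view -> strided, then (N, L_out, k*C)
        wins = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        return np.ascontiguousarray(wins.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, self.kernel * self.in_channels
        )

    def forward(self, x, training=False, rng=None):
        self.x_shape = x.shape
        self.cols = self._cols(x)
        return self.cols @ self.W + self.b

    def backward(self, grad):
        N, L_out, F = grad.shape
        flat = grad.reshape(-1, F)
        self.dW = self.cols.reshape(-1, self.W.shape[0]).T @ flat
        if self.l2:
            self.dW += self.l2 * self.W
        self.db = flat.sum(axis=0)
        dcols = (grad @ self.W.T).reshape(N, L_out, self.kernel, self.in_channels)
        dx = np.zeros(self.x_shape)
        offsets = self.stride * np.arange(L_out)
        for j in range(self.kernel):
            dx[:, offsets + j, :] += dcols[:, :, j, :]
        self.cols = None
        return dx

    def params(self):
        return [(self.W, self.dW, self.l2), (self.b, self.db, 0.0)]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, grad):
        return grad * self.mask


class MaxPool1D(Layer):
    def __init__(self, size, stride=None):
        self.size = size
        self.stride = stride or size

    def out_length(self, L):
        if L < self.size:
            raise ValueError(f"input length {L} shorter than pool size {self.size}")
        return (L - self.size) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        self.x_shape = x.shape
        wins = sliding_window_view(x, self.size, axis=1)[:, :: self.stride]
        self.argmax = wins.argmax(axis=-1)  # (N, L_out, C)
        return wins.max(axis=-1)

    def backward(self, grad):
        N, L_out, C = grad.shape
        dx = np.zeros(self.x_shape)
        n_idx, l_idx, c_idx = np.meshgrid(
            np.arange(N), np.arange(L_out), np.arange(C), indexing="ij"
        )
        pos = self.argmax + self.stride * l_idx
        np.add.at(dx, (n_idx, pos, c_idx), grad)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self.mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self.mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, l2=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.W = (rng.standard_normal((in_features, out_features)) * scale).astype(
            np.float64
        )
        self.b = np.zeros(out_features)
        self.l2 = l2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self.x.T @ grad
        if self.l2:
            self.dW += self.l2 * self.W
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW, self.l2), (self.b, self.db, 0.0)]


class Sigmoid(Layer):
    def forward(self, x, training=False, rng=None):
        self.out = sigmoid(x)
        return self.out

    def backward(self, grad):
        return grad * self.out * (1.0 - self.out)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

class Network:
    """A plain feed-forward stack of layers with scalar output."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_weights(self):
        return [w.copy() for w, _, _ in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for (w, _, _), new in zip(params, weights):
            if w.shape != new.shape:
                raise ValueError(f"shape mismatch {w.shape} vs {new.shape}")
            w[...] = new


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse(pred, target):
    pred, target = _check_pair(pred, target)
    return float(np.mean((pred - target) ** 2))


def weighted_mse(pred, target, threshold: float = 4.0, factor: float = 3.0):
    """Mean of w_i (pred_i - target_i)^2 with w_i = factor where target_i > threshold.

    Up-weights high-signal peaks so the fit does not neglect the strongest
    accessibility sites (defaults: threshold 4, factor 3).
    """
    pred, target = _check_pair(pred, target)
    w = np.where(target > threshold, factor, 1.0)
    return float(np.mean(w * (pred - target) ** 2))


def _check_pair(pred, target):
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal lengths")
    return pred, target


class Loss:
    """Loss with value + gradient w.r.t. the network's raw (linear) output."""

    def value(self, raw, target):
        raise NotImplementedError

    def grad(self, raw, target):
        raise NotImplementedError


class MSELoss(Loss):
    def value(self, raw, target):
        return mse(raw, target)

    def grad(self, raw, target):
        raw_, t = _check_pair(raw, target)
        return (2.0 * (raw_ - t) / raw_.size).reshape(np.shape(raw))


class WeightedMSELoss(Loss):
    def __init__(self, threshold=4.0, factor=3.0):
        self.threshold = threshold
        self.factor = factor

    def value(self, raw, target):
        return weighted_mse(raw, target, self.threshold, self.factor)

    def grad(self, raw, target):
        raw_, t = _check_pair(raw, target)
        w = np.where(t > self.threshold, self.factor, 1.0)
        return (2.0 * w * (raw_ - t) / raw_.size).reshape(np.shape(raw))


class BCEWithLogitsLoss(Loss):
    """Cross-entropy on sigmoid(raw); gradient taken through the sigmoid."""

    def value(self, raw, target):
        raw_, t = _check_pair(raw, target)
        # log(1 + exp(-|x|)) formulation for stability
        return float(
            np.mean(np.maximum(raw_, 0) - raw_ * t + np.log1p(np.exp(-np.abs(raw_))))
        )

    def grad(self, raw, target):
        raw_, t = _check_pair(raw, target)
        return ((sigmoid(raw_) - t) / raw_.size).reshape(np.shape(raw))


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class ConstantLR:
    def __init__(self, lr):
        self.lr = lr

    def __call__(self, step):
        return self.lr


class CyclicLR:
    """Triangular cyclic learning rate oscillating between min_lr and max_lr."""

    def __init__(self, min_lr=1e-3, max_lr=1e-1, period_steps=100):
        if period_steps < 2:
            raise ValueError("period_steps must be >= 2")
        self.min_lr = min_lr
        self.max_lr = max_lr
        self.period_steps = period_steps

    def __call__(self, step):
        phase = (step % self.period_steps) / self.period_steps
        tri = 1.0 - abs(2.0 * phase - 1.0)
        return self.min_lr + (self.max_lr - self.min_lr) * tri


class SGD:
    def __init__(self, network, schedule, momentum=0.0, max_grad_norm=None):
        self.network = network
        self.schedule = schedule
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(w) for w, _, _ in network.params()]
        self.step_count = 0

    def step(self):
        lr = self.schedule(self.step_count)
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g))
                                for _, g, _ in self.network.params()))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / total
                for _, g, _ in self.network.params():
                    g *= scale
        for v, (w, g, _l2) in zip(self.velocity, self.network.params()):
            if self.momentum:
                v *= self.momentum
                v -= lr * g
                w += v
            else:
                w -= lr * g
        self.step_count += 1
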