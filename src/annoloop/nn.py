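"""Minimal numpy neural-network layers with explicit forward/backward passes.

The segmentation network used throughout the package is small (order 1e5
parameters) and runs on CPU, so the layers here favour clarity over raw
throughput: 3x3 convolutions are computed as nine shifted channel-mixing
products, pooling uses reshape tricks, and every layer caches exactly what
its backward pass needs.

Array convention: activations are float64 arrays of shape (N, C, H, W).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: subclasses implement forward/backward and expose params."""

    def params(self) -> dict[str, Param]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2-D convolution with square kernel and stride 1.

    Weight shape is (out_channels, in_channels, k, k); He-normal init.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant")
        out = np.empty((n, self.cout, h, w))
        out[:] = self.b.value[None, :, None, None]
        for ki in range(self.k):
            for kj in range(self.k):
                # (O,C) x (N,C,H,W) -> (O,N,H,W)
                contrib = np.tensordot(
                    self.w.value[:, :, ki, kj], xp[:, :, ki : ki + h, kj : kj + w], axes=([1], [1])
                )
                out += contrib.transpose(1, 0, 2, 3)
        self._cache = (xp, x.shape)
        return out

    def backward(self, dout):
        xp, xshape = self._cache
        n, c, h, w = xshape
        p = self.k // 2
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xp[:, :, ki : ki + h, kj : kj + w]
                # dW: (N,O,H,W) x (N,C,H,W) summed over N,H,W
                self.w.grad[:, :, ki, kj] += np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
                contrib = np.tensordot(self.w.value[:, :, ki, kj], dout, axes=([0], [1]))
                dxp[:, :, ki : ki + h, kj : kj + w] += contrib.transpose(1, 0, 2, 3)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling).

    Weight shape follows the (in_channels, out_channels, 2, 2) convention.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        fan_in = cin  # each output pixel sees one input pixel per channel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, train):
        n, c, h, w = x.shape
        # y[n,o,2h+a,2w+b] = sum_c W[c,o,a,b] x[n,c,h,w]
        y = np.einsum("nchw,coab->nohawb", x, self.w.value, optimize=True)
        y = y.reshape(n, self.cout, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dout):
        x = self._cache
        n, c, h, w = x.shape
        d = dout.reshape(n, self.cout, h, 2, w, 2)
        self.w.grad += np.einsum("nchw,nohawb->coab", x, d, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("nohawb,coab->nchw", d, self.w.value, optimize=True)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) with affine parameters.

    Running statistics are buffers (not trainable) and are used in eval mode.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv_std[None, :, None, None]
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term -= xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; input spatial dims must be even."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def buffers(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, b in layer.buffers().items():
                out[f"{i}.{name}"] = b
        return out

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a flat dict of Params."""

    def __init__(self, params: dict[str, Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_ignore(logits: np.ndarray, labels: np.ndarray,
                         ignore_value: int = -1) -> tuple[float, np.ndarray]:
    """Per-pixel 2-class cross entropy; pixels labelled ``ignore_value`` carry
    no loss and no gradient.

    logits: (N, K, H, W); labels: (N, H, W) integer class ids or ignore_value.
    Loss is averaged over the labelled pixels only, so adding unlabelled
    pixels (or whole unlabelled patches) leaves both loss and gradients
    unchanged. Returns (loss, dlogits); with zero labelled pixels the loss is
    0.0 and the gradient identically zero.
    """
    n, k, h, w = logits.shape
    valid = labels != ignore_value
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    probs = softmax(logits, axis=1)
    safe_labels = np.where(valid, labels, 0)
    onehot = np.eye(k)[safe_labels].transpose(0, 3, 1, 2)
    picked = np.clip((probs * onehot).sum(axis=1), 1e-12, None)
    loss = -(np.log(picked)[valid]).sum() / n_valid
    dlogits = (probs - onehot) * valid[:, None, :, :] / n_valid
    return float(loss), dlogits


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size
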