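"""Minimal layer-based neural-network backend on numpy.

Volumes travel through the network in channels-last layout ``(N, D, H, W, C)``
so that every convolution reduces to a handful of BLAS matmuls (one per kernel
offset).  Each layer caches what its backward pass needs; calling
:meth:`Module.backward` with the gradient of a scalar loss w.r.t. the layer
output returns the gradient w.r.t. the layer input and accumulates parameter
gradients in place.

Two field-specific hooks live here rather than in a general autodiff engine:

* ``ReLU`` supports a *guided* backward mode in which the upstream gradient is
  additionally gated to its positive part — the double-gating rule of guided
  backpropagation (zero relevance wherever the forward pre-activation or the
  incoming relevance is non-positive).
* ``GradientReversal`` is the identity on the forward pass and multiplies the
  incoming gradient by ``-lambda`` on the backward pass (domain-adversarial
  training).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv3d",
    "BatchNorm",
    "ReLU",
    "AvgPool3d",
    "GlobalAvgPool",
    "Dropout",
    "Linear",
    "GradientReversal",
    "Sequential",
    "Concat",
    "softmax",
    "cross_entropy",
    "set_guided",
    "set_lambda",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    def parameters(self) -> list[Param]:
        return []

    def modules(self):
        yield self

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Conv3d(Module):
    """3D convolution, stride 1, 'same' zero padding, kernel 1 or 3."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel**3, c_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._x_pad: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, d, h, w_, c = x.shape
        k = self.kernel
        if k == 1:
            self._x_pad = x
            y = x.reshape(-1, c) @ self.w.value[0] + self.b.value
            return y.reshape(n, d, h, w_, self.c_out)
        p = 1
        xp = np.zeros((n, d + 2 * p, h + 2 * p, w_ + 2 * p, c), dtype=DTYPE)
        xp[:, p:-p, p:-p, p:-p, :] = x
        self._x_pad = xp
        y = np.empty((n * d * h * w_, self.c_out), dtype=DTYPE)
        y[:] = self.b.value
        idx = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sl = xp[:, dz : dz + d, dy : dy + h, dx : dx + w_, :]
                    y += np.ascontiguousarray(sl).reshape(-1, c) @ self.w.value[idx]
                    idx += 1
        return y.reshape(n, d, h, w_, self.c_out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, d, h, w_, _ = gout.shape
        g2 = gout.reshape(-1, self.c_out)
        self.b.grad += g2.sum(axis=0)
        k = self.kernel
        if k == 1:
            x2 = self._x_pad.reshape(-1, self.c_in)
            self.w.grad[0] += x2.T @ g2
            gin = g2 @ self.w.value[0].T
            return gin.reshape(n, d, h, w_, self.c_in)
        xp = self._x_pad
        gxp = np.zeros_like(xp)
        idx = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sl = xp[:, dz : dz + d, dy : dy + h, dx : dx + w_, :]
                    self.w.grad[idx] += np.ascontiguousarray(sl).reshape(-1, self.c_in).T @ g2
                    gxp[:, dz : dz + d, dy : dy + h, dx : dx + w_, :] += (
                        g2 @ self.w.value[idx].T
                    ).reshape(n, d, h, w_, self.c_in)
                    idx += 1
        return gxp[:, 1:-1, 1:-1, 1:-1, :]


class BatchNorm(Module):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(DTYPE), train, x.shape)
        return (xhat * self.gamma.value + self.beta.value).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        axes = tuple(range(gout.ndim - 1))
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = gout * self.gamma.value
        if not train:
            return (g * inv).astype(DTYPE)
        m = np.prod([shape[a] for a in axes])
        gmean = g.mean(axis=axes)
        gdot = (g * xhat).mean(axis=axes)
        return ((g - gmean - xhat * gdot) * inv).astype(DTYPE)


class ReLU(Module):
    """Rectifier; ``guided`` flips the backward pass to guided-backprop gating."""

    guided = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, 0.0).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._pos, gout, 0.0)
        if self.guided:
            g = np.where(g > 0, g, 0.0)
        return g.astype(DTYPE)


class AvgPool3d(Module):
    """2x2x2 average pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, d, h, w, c = x.shape
        self._shape = x.shape
        y = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4, 6))
        return y.astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        g = gout[:, :, None, :, None, :, None, :] / 8.0
        g = np.broadcast_to(g, (n, d // 2, 2, h // 2, 2, w // 2, 2, c))
        return g.reshape(n, d, h, w, c).astype(DTYPE)


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        g = gout[:, None, None, None, :] / (d * h * w)
        return np.broadcast_to(g, self._shape).astype(DTYPE)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return (gout @ self.w.value.T).astype(DTYPE)


class GradientReversal(Module):
    """Identity forward; backward multiplies the gradient by ``-lambda``."""

    def __init__(self, lam: float = 0.0):
        self.lam = float(lam)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return (-self.lam) * gout


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in l.parameters()]

    def modules(self):
        yield self
        for l in self.layers:
            yield from l.modules()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class Concat(Module):
    """Channel-wise concatenation of the input with a branch applied to it.

    This is the dense-connectivity primitive: the output of a dense layer is
    concatenated with its own input, so later layers see all earlier feature
    maps of the block.
    """

    def __init__(self, branch: Module):
        self.branch = branch

    def parameters(self) -> list[Param]:
        return self.branch.parameters()

    def modules(self):
        yield self
        yield from self.branch.modules()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._c_in = x.shape[-1]
        y = self.branch.forward(x, train=train)
        return np.concatenate([x, y], axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = gout[..., : self._c_in]
        gy = gout[..., self._c_in :]
        return (gx + self.branch.backward(np.ascontiguousarray(gy))).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def set_guided(model: Module, on: bool) -> None:
    for m in model.modules():
        if isinstance(m, ReLU):
            m.guided = on


def set_lambda(model: Module, lam: float) -> None:
    for m in model.modules():
        if isinstance(m, GradientReversal):
            m.lam = float(lam)
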