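"""Minimal numpy neural-network layers with hand-written backpropagation.

Implements exactly what the emission scorers need: 1D/2D same-padding
convolutions, instance normalization, ReLU, residual blocks and an Adam
optimizer.  Arrays are channels-last (``(L, C)`` for 1D, ``(H, W, C)`` for
2D) in float64; every forward pass caches what its backward pass needs.
Parameter initialization is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "Conv2D",
    "InstanceNorm",
    "ReLU",
    "ResidualBlock",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self):
        for name in getattr(self, "_params", ()):
            yield name, getattr(self, name)
        for name in getattr(self, "_children", ()):
            child = getattr(self, name)
            for sub, p in child.parameters():
                yield f"{name}.{sub}", p

    def zero_grad(self):
        for _n, p in self.parameters():
            p.grad[...] = 0.0


class Conv1D(Module):
    """Same-padding 1D convolution on ``(L, C_in) -> (L, C_out)``."""

    _params = ("W", "b")

    def __init__(self, c_in, c_out, k, rng):
        assert k % 2 == 1
        self.k, self.c_in, self.c_out = k, c_in, c_out
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def forward(self, x):
        L = x.shape[0]
        pad = self.k // 2
        xp = np.pad(x, ((pad, pad), (0, 0)))
        cols = np.stack([xp[d : d + L] for d in range(self.k)], axis=1)
        cols = cols.reshape(L, self.k * self.c_in)
        self._cache = (cols, L)
        return cols @ self.W.value.reshape(-1, self.c_out) + self.b.value

    def backward(self, dy):
        cols, L = self._cache
        pad = self.k // 2
        self.W.grad += (cols.T @ dy).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=0)
        dcols = (dy @ self.W.value.reshape(-1, self.c_out).T).reshape(
            L, self.k, self.c_in
        )
        dxp = np.zeros((L + 2 * pad, self.c_in))
        for d in range(self.k):
            dxp[d : d + L] += dcols[:, d]
        return dxp[pad : pad + L]


class Conv2D(Module):
    """Same-padding 2D convolution on ``(H, W, C_in) -> (H, W, C_out)``."""

    _params = ("W", "b")

    def __init__(self, c_in, c_out, k, rng):
        assert k % 2 == 1
        self.k, self.c_in, self.c_out = k, c_in, c_out
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def forward(self, x):
        H, Wd = x.shape[:2]
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
        cols = np.empty((H, Wd, k, k, self.c_in))
        for a in range(k):
            for b in range(k):
                cols[:, :, a, b] = xp[a : a + H, b : b + Wd]
        cols = cols.reshape(H * Wd, k * k * self.c_in)
        self._cache = (cols, H, Wd)
        y = cols @ self.W.value.reshape(-1, self.c_out) + self.b.value
        return y.reshape(H, Wd, self.c_out)

    def backward(self, dy):
        cols, H, Wd = self._cache
        k, pad = self.k, self.k // 2
        dyf = dy.reshape(H * Wd, self.c_out)
        self.W.grad += (cols.T @ dyf).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.reshape(-1, self.c_out).T).reshape(
            H, Wd, k, k, self.c_in
        )
        dxp = np.zeros((H + 2 * pad, Wd + 2 * pad, self.c_in))
        for a in range(k):
            for b in range(k):
                dxp[a : a + H, b : b + Wd] += dcols[:, :, a, b]
        return dxp[pad : pad + H, pad : pad + Wd]


class InstanceNorm(Module):
    """Per-channel normalization over all spatial positions, with affine."""

    _params = ("gamma", "beta")

    def __init__(self, c, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, axes, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, ivar, axes, shape = self._cache
        n = int(np.prod([shape[a] for a in axes]))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        # d/dx of (x - mu) / sqrt(var + eps) over the normalization axes
        return (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * ivar


class ReLU(Module):
    def forward(self, x):
        self._cache = x > 0
        return x * self._cache

    def backward(self, dy):
        return dy * self._cache


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)
        self._children = tuple(f"m{k}" for k in range(len(modules)))
        for k, m in enumerate(modules):
            setattr(self, f"m{k}", m)

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


class ResidualBlock(Module):
    """``y = body(x) + x`` where body is conv [+ norm] + ReLU repeated."""

    def __init__(self, body: Sequential):
        self.body = body
        self._children = ("body",)

    def forward(self, x):
        return self.body.forward(x) + x

    def backward(self, dy):
        return self.body.backward(dy) + dy


def conv_stack(conv_cls, c_in, width, k, n_convs, rng, use_norm=True):
    """Projection layer followed by residual pairs totalling ``n_convs``
    convolutions (an odd count appends one extra plain unit)."""

    def unit(cin, cout):
        mods = [conv_cls(cin, cout, k, rng)]
        if use_norm:
            mods.append(InstanceNorm(cout))
        mods.append(ReLU())
        return mods

    layers = unit(c_in, width)
    remaining = n_convs - 1
    for _ in range(remaining // 2):
        layers.append(ResidualBlock(Sequential(*(unit(width, width) + unit(width, width)))))
    if remaining % 2:
        layers.extend(unit(width, width))
    return Sequential(*layers)


def residual_net2d(c_in, width, k, n_blocks, convs_per_block, out_channels,
                   rng, use_norm=True):
    """2D ResNet: projection, ``n_blocks`` residual blocks of
    ``convs_per_block`` conv units each, then a 1x1 head."""
    mods = [Conv2D(c_in, width, k, rng)]
    if use_norm:
        mods.append(InstanceNorm(width))
    mods.append(ReLU())
    for _ in range(n_blocks):
        units = []
        for _ in range(convs_per_block):
            units.append(Conv2D(width, width, k, rng))
            if use_norm:
                units.append(InstanceNorm(width))
            units.append(ReLU())
        mods.append(ResidualBlock(Sequential(*units)))
    mods.append(Conv2D(width, out_channels, 1, rng))
    return Sequential(*mods)


class Adam:
    """Adam on a module's parameters (minimizes the loss whose gradient is
    accumulated in ``param.grad``)."""

    def __init__(self, module: Module, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.module = module
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p.value) for n, p in module.parameters()}
        self.v = {n: np.zeros_like(p.value) for n, p in module.parameters()}

    def step(self):
        self.t += 1
        for n, p in self.module.parameters():
            g = p.grad
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1 ** self.t)
            vhat = self.v[n] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain gradient descent, for full-batch ascent-monotonicity checks."""

    def __init__(self, module: Module, lr=1e-2):
        self.module = module
        self.lr = lr

    def step(self):
        for _n, p in self.module.parameters():
            p.value -= self.lr * p.grad
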