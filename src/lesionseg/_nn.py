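"""Minimal NumPy layer stack with explicit backprop for the 2.5D backbone.

Deliberately small: 3x3/1x1 convolutions, ReLU, 2x2 max pooling, nearest
upsampling, the normalization layer (delegating statistics semantics to
:mod:`lesionseg.normalization`), a sigmoid head, and Adam.  Everything is
float64 and fully deterministic, which makes seed-exact training runs and
bit-identical checkpoint round-trips straightforward.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .normalization import (
    NormalizationState,
    normalize_eval_bn,
    normalize_train,
    normalize_ttin,
)


class Conv2d:
    """Same-padded k x k convolution (k odd). He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xpad: Optional[np.ndarray] = None

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, H, W = x.shape
        y = np.zeros((n, self.W.shape[0], H, W))
        for i in range(self.k):
            for j in range(self.k):
                y += np.einsum("nchw,oc->nohw", xpad[:, :, i : i + H, j : j + W], self.W[:, :, i, j])
        y += self.b[None, :, None, None]
        if train:
            self._xpad = xpad
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        n, _, H, W = gy.shape
        p = self.k // 2
        gxpad = np.zeros_like(xpad)
        for i in range(self.k):
            for j in range(self.k):
                self.gW[:, :, i, j] += np.einsum("nohw,nchw->oc", gy, xpad[:, :, i : i + H, j : j + W])
                gxpad[:, :, i : i + H, j : j + W] += np.einsum("nohw,oc->nchw", gy, self.W[:, :, i, j])
        self.gb += gy.sum(axis=(0, 2, 3))
        self._xpad = None
        return gxpad[:, :, p : p + H, p : p + W] if p else gxpad


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy):
        gy = gy * self._mask
        self._mask = None
        return gy


class MaxPool2:
    """2x2, stride 2; input extents must be even."""

    def __init__(self):
        self._arg = None
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x, train):
        n, c, H, W = x.shape
        xb = x.reshape(n, c, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, H // 2, W // 2, 4)
        arg = xb.argmax(axis=-1)
        y = np.take_along_axis(xb, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._shape = arg, x.shape
        return y

    def backward(self, gy):
        n, c, H, W = self._shape
        gb = np.zeros((n, c, H // 2, W // 2, 4))
        np.put_along_axis(gb, self._arg[..., None], gy[..., None], axis=-1)
        gx = gb.reshape(n, c, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, H, W)
        self._arg = self._shape = None
        return gx


class UpsampleNearest2:
    def parameters(self):
        return []

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, H, W = gy.shape
        return gy.reshape(n, c, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class NormLayer:
    """Feature normalization with trainable (gamma, beta); see normalization module.

    At inference the statistics source is chosen per the (mode, use_ttin)
    pair: instance statistics for IN/CondIN or whenever TTIN is on, moving
    averages for BN with TTIN off.  Batched inference is allowed because
    instance statistics are computed per item and BN moving statistics are
    input-independent, so results equal slice-at-a-time processing.
    """

    def __init__(self, mode: str, c: int):
        self.state = NormalizationState.create(mode, c)
        self.ggamma = np.zeros_like(self.state.gamma)
        self.gbeta = np.zeros_like(self.state.beta)
        self._cache = None

    def parameters(self):
        return [(self.state.gamma, self.ggamma), (self.state.beta, self.gbeta)]

    def forward(self, x, train, combos=None, use_ttin=False):
        st = self.state
        if train:
            y, self._cache = normalize_train(x, st, combos, update_stats=True, return_cache=True)
            return y
        if st.mode == "BN" and not use_ttin:
            return normalize_eval_bn(x, st)
        if x.shape[0] == 1:
            return normalize_ttin(x, st, combos if combos is None else int(np.asarray(combos).flat[0]))
        # batched instance statistics: identical per-item to TTIN one at a time
        return normalize_train(x, st, combos, update_stats=False)

    def backward(self, gy):
        xhat, var, g, combos = self._cache
        st = self.state
        if st.mode == "BN":
            axes = (0, 2, 3)
            m = np.prod([gy.shape[a] for a in axes])
            self.ggamma += (gy * xhat).sum(axis=axes)
            self.gbeta += gy.sum(axis=axes)
            gxhat = gy * g[None, :, None, None]
            gmean = gxhat.mean(axis=axes, keepdims=True)
            gdot = (gxhat * xhat).mean(axis=axes, keepdims=True)
            gx = (gxhat - gmean - xhat * gdot) / np.sqrt(var[None, :, None, None] + st.eps)
        else:
            per_item_g = (gy * xhat).sum(axis=(2, 3))  # (n, c)
            per_item_b = gy.sum(axis=(2, 3))
            if st.mode == "CondIN":
                for i, cb in enumerate(combos):
                    self.ggamma[int(cb) - 1] += per_item_g[i]
                    self.gbeta[int(cb) - 1] += per_item_b[i]
            else:
                self.ggamma += per_item_g.sum(axis=0)
                self.gbeta += per_item_b.sum(axis=0)
            gxhat = gy * g[:, :, None, None]
            gmean = gxhat.mean(axis=(2, 3), keepdims=True)
            gdot = (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
            gx = (gxhat - gmean - xhat * gdot) / np.sqrt(var + st.eps)
        self._cache = None
        return gx


class Sigmoid:
    def __init__(self):
        self._y = None

    def parameters(self):
        return []

    def forward(self, x, train):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, gy):
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


class Adam:
    """Standard Adam over (value, grad) parameter pairs (in-place updates)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
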