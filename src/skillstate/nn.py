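"""Minimal channels-last neural-network primitives (numpy, CPU).

Implements exactly the layers the 3-D EEG classifier needs — strided valid
3-D convolution (im2col + BLAS matmul), batch normalization, ReLU,
dropout, dense layers, temporal attentive pooling, and a softmax
cross-entropy head — each with a hand-written backward pass, plus Adam.
Gradients of every layer are validated against central finite differences
in the test suite.

Tensors are ``(batch, height, width, time, channels)`` float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "TemporalAttentivePooling",
    "softmax",
    "softmax_xent",
    "Adam",
    "glorot_uniform",
]

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int
                   ) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base layer: ``params``/``grads`` are parallel dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv3D(Layer):
    """Valid (unpadded) strided 3-D convolution over (h, w, t)."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        super().__init__()
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.in_ch, self.out_ch = in_ch, out_ch
        k = int(np.prod(kernel)) * in_ch
        self.params["W"] = glorot_uniform(
            rng, (in_ch, *kernel, out_ch), k, int(np.prod(kernel)) * out_ch
        )
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    def out_shape(self, in_shape):
        return tuple(
            (s - k) // st + 1
            for s, k, st in zip(in_shape, self.kernel, self.stride)
        )

    def forward(self, x, train):
        kh, kw, kt = self.kernel
        sh, sw, st = self.stride
        B = x.shape[0]
        view = np.lib.stride_tricks.sliding_window_view(
            x, (kh, kw, kt), axis=(1, 2, 3)
        )  # (B, H-kh+1, W-kw+1, T-kt+1, C, kh, kw, kt)
        view = view[:, ::sh, ::sw, ::st]
        self._oshape = view.shape[1:4]
        P = np.ascontiguousarray(view).reshape(-1, self.in_ch * kh * kw * kt)
        self._P = P
        self._xshape = x.shape
        Wmat = self.params["W"].reshape(P.shape[1], self.out_ch)
        y = P @ Wmat + self.params["b"]
        return y.reshape(B, *self._oshape, self.out_ch)

    def backward(self, dy):
        kh, kw, kt = self.kernel
        sh, sw, st = self.stride
        B, oh, ow, ot, _ = dy.shape
        dyf = dy.reshape(-1, self.out_ch)
        self.grads["W"] = (self._P.T @ dyf).reshape(self.params["W"].shape)
        self.grads["b"] = dyf.sum(axis=0)
        W = self.params["W"]  # (C, kh, kw, kt, O)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        for i in range(kh):
            for j in range(kw):
                for k in range(kt):
                    # (N, O) @ (O, C) scattered back to the input slices
                    contrib = (dyf @ W[:, i, j, k, :].T).reshape(
                        B, oh, ow, ot, self.in_ch
                    )
                    dx[
                        :,
                        i : i + oh * sh : sh,
                        j : j + ow * sw : sw,
                        k : k + ot * st : st,
                        :,
                    ] += contrib
        self._P = None
        return dx


class BatchNorm(Layer):
    """Normalization over every axis but the last (feature channels)."""

    def __init__(self, n_ch, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_ch, dtype=F32)
        self.params["beta"] = np.zeros(n_ch, dtype=F32)
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._train = train
        self._n = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        if not self._train:
            # eval mode: fixed affine transform, no batch-statistic terms
            return (dxhat / std).astype(dy.dtype, copy=False)
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) / std
        return dx.astype(dy.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class TemporalAttentivePooling(Layer):
    """Collapse the temporal axis by learned softmax attention.

    Spatial attentive pooling first: the (h, w, t, ch) feature is weighted
    elementwise by the trainable tensor ``phi`` and summed over space,
    giving a (t, ch) summary; channels are averaged to a length-t vector,
    passed through a dense t -> t map, and softmaxed into attention
    weights that sum to one over time.  The output is the
    attention-weighted temporal sum, shape (h, w, 1, ch).
    """

    def __init__(self, feat_shape, rng):
        super().__init__()
        h, w, t, c = feat_shape
        self.feat_shape = feat_shape
        self.params["phi"] = np.ones((h, w, t, c), dtype=F32)
        self.params["Wt"] = glorot_uniform(rng, (t, t), t, t)
        self.params["bt"] = np.zeros(t, dtype=F32)

    def forward(self, x, train):
        self._x = x
        phi = self.params["phi"]
        S = (x * phi).sum(axis=(1, 2))                     # (B, t, c)
        u = S.mean(axis=2)                                 # (B, t)
        logits = u @ self.params["Wt"] + self.params["bt"]
        a = softmax(logits, axis=1)                        # (B, t)
        self._S, self._u, self._a = S, u, a
        y = np.einsum("bhwtc,bt->bhwc", x, a)
        return y[:, :, :, None, :]

    @property
    def attention(self) -> np.ndarray:
        """Last batch's attention weights (B, t)."""
        return self._a

    def backward(self, dy):
        x, a = self._x, self._a
        c = x.shape[-1]
        dyc = dy[:, :, :, 0, :]                            # (B, h, w, c)
        dx = np.einsum("bhwc,bt->bhwtc", dyc, a)
        da = np.einsum("bhwc,bhwtc->bt", dyc, x)
        dlogits = a * (da - (a * da).sum(axis=1, keepdims=True))
        self.grads["Wt"] = self._u.T @ dlogits
        self.grads["bt"] = dlogits.sum(axis=0)
        du = dlogits @ self.params["Wt"].T                 # (B, t)
        dS = np.repeat(du[:, :, None] / c, c, axis=2)      # (B, t, c)
        phi = self.params["phi"]
        dx = dx + phi[None] * dS[:, None, None, :, :]
        self.grads["phi"] = np.einsum("bhwtc,btc->hwtc", x, dS)
        return dx


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray
                 ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch.

    Returns (loss, probabilities, dlogits) where dlogits is the gradient
    of the mean loss.
    """
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, p, (d / n).astype(logits.dtype, copy=False)


class Adam:
    """Adam over a list of layers' parameter dicts."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for li, layer in enumerate(self.layers):
            for k, g in layer.grads.items():
                m = self.m[li][k]
                v = self.v[li][k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                layer.params[k] -= (
                    self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
                ).astype(layer.params[k].dtype, copy=False)
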