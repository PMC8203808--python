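"""Differentiable layers (forward + hand-derived backward) on numpy arrays.

Data layout is channels-first: (N, C, D, H, W), float32. Convolutions use
'same' padding (output extent = ceil(input / stride), extra padding on the
high side, as in common DL frameworks). The backward pass of the k^3
convolution is expressed as k^3 strided slice-accumulations, which keeps
everything in BLAS-friendly tensordot calls.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list:
        """List of (name, value_array, grad_array) triples; grads may be None."""
        return []


def _same_pad(extent: int, stride: int, k: int) -> tuple[int, int, int]:
    out = -(-extent // stride)
    total = max((out - 1) * stride + k - extent, 0)
    return out, total // 2, total - total // 2


class Conv3D(Layer):
    """3D convolution, kernel k^3, stride s, 'same' padding, optional bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.W = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, D, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        s, k = self.stride, self.k
        od, pd0, pd1 = _same_pad(D, s, k)
        oh, ph0, ph1 = _same_pad(H, s, k)
        ow, pw0, pw1 = _same_pad(W, s, k)
        xp = np.pad(x, ((0, 0), (0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1)))
        out = np.zeros((N, self.c_out, od, oh, ow), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s]
                    # (N,C,od,oh,ow) x (O,C) -> accumulate (N,O,od,oh,ow)
                    out += np.einsum("ncdhw,oc->nodhw", xs, self.W[:, :, i, j, l],
                                     optimize=True)
        if self.b is not None:
            out += self.b[None, :, None, None, None]
        self._cache = (xp, x.shape, (od, oh, ow), (pd0, ph0, pw0))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape, (od, oh, ow), (pd0, ph0, pw0) = self._cache
        s, k = self.stride, self.k
        dxp = np.zeros_like(xp)
        self.dW.fill(0.0)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s]
                    self.dW[:, :, i, j, l] = np.einsum(
                        "nodhw,ncdhw->oc", dout, xs, optimize=True)
                    dxp[:, :, i:i + s * od:s, j:j + s * oh:s, l:l + s * ow:s] += (
                        np.einsum("nodhw,oc->ncdhw", dout, self.W[:, :, i, j, l],
                                  optimize=True))
        if self.b is not None:
            self.db[...] = dout.sum(axis=(0, 2, 3, 4))
        _, _, D, H, W = xshape
        return dxp[:, :, pd0:pd0 + D, ph0:ph0 + H, pw0:pw0 + W]

    def params(self) -> list:
        out = [("W", self.W, self.dW)]
        if self.b is not None:
            out.append(("b", self.b, self.db))
        return out


class BatchNorm3D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, x.shape, training)
        return (self.gamma[None, :, None, None, None] * xhat
                + self.beta[None, :, None, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape, training = self._cache
        axes = (0, 2, 3, 4)
        self.dgamma[...] = np.sum(dout * xhat, axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self.gamma[None, :, None, None, None] * inv[None, :, None, None, None]
        if not training:
            return dout * g
        m = shape[0] * shape[2] * shape[3] * shape[4]
        dxhat = dout * self.gamma[None, :, None, None, None]
        term = (dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return term * inv[None, :, None, None, None]

    def params(self) -> list:
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def running_stats(self) -> list:
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class ReLU(Layer):
    """ReLU with an optional guided-backprop backward rule.

    In guided mode the backward signal is zeroed wherever either the forward
    activation or the backward signal itself is negative.
    """

    def __init__(self):
        self._mask = None
        self.guided = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        if self.guided:
            dx = np.where(dx > 0, dx, 0.0)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, D, H, W = self._shape
        scale = 1.0 / (D * H * W)
        return (np.broadcast_to(dout[:, :, None, None, None], self._shape)
                * scale).astype(np.float32)


class Dense(Layer):
    """Fully connected layer on (N, F) features."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((f_in, f_out))
                  * np.sqrt(2.0 / f_in)).astype(np.float32)
        self.b = np.zeros(f_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return (dout @ self.W.T).astype(np.float32)

    def params(self) -> list:
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy on one-hot labels and its logit gradient."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    return float(loss), ((p - onehot) / n).astype(np.float32)
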