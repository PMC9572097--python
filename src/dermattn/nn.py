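"""Minimal differentiable layers on numpy arrays.

All layers operate on float64 arrays in NHWC layout (batch, height, width,
channels) and implement an explicit reverse pass: ``forward`` caches what the
backward pass needs, ``backward`` returns the gradient with respect to the
input and accumulates parameter gradients in ``Param.grad``.  The explicit
style keeps every gradient checkable against finite differences, which the
test suite does for each layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
]


class Param:
    """A learnable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    """Fully connected layer y = x @ W + b for 2-D inputs (N, in_dim)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 name: str = "dense") -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(_glorot(rng, (in_dim, out_dim), in_dim, out_dim), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.W.value.shape[0]:
            raise ValueError(
                f"dense layer expects (N, {self.W.value.shape[0]}) input, got {x.shape}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def _pad_same(x: np.ndarray, kh: int, kw: int, fill: str) -> tuple[np.ndarray, int, int]:
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    mode = "constant" if fill == "zeros" else "edge"
    return np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)), mode=mode), ph, pw


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-kh+1, W-kw+1, kh*kw*C) patch matrix (stride 1)."""
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, oh, ow, kh * kw * c)


class Conv2D(Layer):
    """Stride-1 2-D convolution over NHWC input, spanning the full channel depth.

    ``padding='same'`` preserves the spatial dimensions; ``'valid'`` applies no
    padding.  ``pad_fill`` chooses what same-padding sees outside the input:
    ``'zeros'`` or ``'edge'`` (replicate the border pixel, which keeps a
    constant input constant under the convolution).  Kernel weights have
    shape (kh, kw, in_ch, out_ch).
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, padding: str = "same",
                 pad_fill: str = "zeros", rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if pad_fill not in ("zeros", "edge"):
            raise ValueError(f"unknown pad_fill {pad_fill!r}")
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * in_ch
        self.W = Param(_glorot(rng, (ksize, ksize, in_ch, out_ch), fan_in, out_ch), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self.ksize = ksize
        self.padding = padding
        self.pad_fill = pad_fill
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[3] != self.W.value.shape[2]:
            raise ValueError(f"conv expects (N,H,W,{self.W.value.shape[2]}), got {x.shape}")
        k = self.ksize
        if self.padding == "same":
            xp, _, _ = _pad_same(x, k, k, self.pad_fill)
        else:
            if x.shape[1] < k or x.shape[2] < k:
                raise ValueError(
                    f"spatial dims {x.shape[1:3]} smaller than kernel {k}x{k}"
                )
            xp = x
        cols = _im2col(xp, k, k)  # (N, OH, OW, k*k*Cin)
        wmat = self.W.value.reshape(-1, self.W.value.shape[3])
        out = cols @ wmat + self.b.value
        self._cache = (x.shape, cols)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        k = self.ksize
        cin, cout = self.W.value.shape[2], self.W.value.shape[3]
        n, oh, ow = dout.shape[:3]
        dmat = dout.reshape(-1, cout)
        self.W.grad += (cols.reshape(-1, k * k * cin).T @ dmat).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        # input gradient as a full correlation: dxp = dout (*) flip(W)^T
        if self.padding == "same":
            ph, pw = (k - 1) // 2, (k - 1) // 2
            hp, wp = x_shape[1] + k - 1, x_shape[2] + k - 1
        else:
            ph = pw = 0
            hp, wp = x_shape[1], x_shape[2]
        dpad = np.zeros((n, oh + 2 * (k - 1), ow + 2 * (k - 1), cout))
        dpad[:, k - 1:k - 1 + oh, k - 1:k - 1 + ow, :] = dout
        wflip = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, cin)
        dxp = _im2col(dpad, k, k) @ wflip  # (n, hp, wp, cin)
        h, w = x_shape[1], x_shape[2]
        if self.padding == "same" and self.pad_fill == "edge":
            # fold gradients on replicated pad pixels back onto the border
            top, bottom = ph, hp - ph - h
            folded = dxp[:, ph:ph + h]
            if top:
                folded[:, 0] += dxp[:, :ph].sum(axis=1)
            if bottom:
                folded[:, h - 1] += dxp[:, ph + h:].sum(axis=1)
            left, right = pw, wp - pw - w
            out = folded[:, :, pw:pw + w]
            if left:
                out[:, :, 0] += folded[:, :, :pw].sum(axis=2)
            if right:
                out[:, :, w - 1] += folded[:, :, pw + w:].sum(axis=2)
            return out
        return dxp[:, ph:ph + h, pw:pw + w, :]


class MaxPool2D(Layer):
    """Non-overlapping 2-D max pooling (window == stride), NHWC."""

    def __init__(self, window: int = 2) -> None:
        self.window = window
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        w = self.window
        n, h, wd, c = x.shape
        oh, ow = h // w, wd // w
        if oh == 0 or ow == 0:
            raise ValueError(f"input {x.shape} smaller than pool window {w}")
        xt = x[:, :oh * w, :ow * w, :].reshape(n, oh, w, ow, w, c)
        # windows flattened last so one argmax picks the (first) max per cell
        xw = np.ascontiguousarray(xt.transpose(0, 1, 3, 5, 2, 4)).reshape(n, oh, ow, c, w * w)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        w = self.window
        n, oh, ow, c = dout.shape
        dxw = np.zeros((n, oh, ow, c, w * w))
        np.put_along_axis(dxw, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :oh * w, :ow * w, :] = (
            dxw.reshape(n, oh, ow, c, w, w).transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, oh * w, ow * w, c))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dropout probability must be in [0,1], got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return np.asarray(x, dtype=np.float64)
        if self.p == 1.0:
            self._mask = np.zeros_like(x)
            return np.zeros_like(x)
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer; ``epsilon`` defaults to the large value used for this
    architecture family (0.1), which damps the per-parameter rescaling."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, epsilon: float = 0.1) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.epsilon = beta1, beta2, epsilon
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.epsilon)
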