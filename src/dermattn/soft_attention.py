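"""Soft-attention over convolutional feature maps.

Given a feature tensor t ∈ R^{h×w×d}, a learned convolution produces K score
maps which are softmax-normalized *jointly over the h·w spatial positions* of
each map, so each attention map is a probability distribution over image
locations.  The K maps are summed into an aggregate weight field α (which
sums to K), t is modulated location-wise by α and scaled by a learnable
scalar γ, and the layer output is the concatenation of t with the scaled
branch along the channel axis:

    f_sa(t) = concat(t,  γ · t ⊙ α),   α = Σ_k softmax(conv_k(t))

The surrounding module applies ReLU to the incoming feature map, max-pools
both the plain and the attended path, concatenates them, and finishes with
ReLU + dropout.  Attention lets the classifier upweight the lesion region
and suppress surrounding skin without any localization supervision.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2D, Dropout, Layer, MaxPool2D, Param, ReLU

__all__ = [
    "SoftAttention",
    "SoftAttentionModule",
    "attention_maps",
    "attention_aggregate",
    "soft_attention_forward",
    "sa_module_forward",
]


def _as_batch(t: np.ndarray) -> tuple[np.ndarray, bool]:
    t = np.asarray(t, dtype=np.float64)
    if t.ndim == 3:
        return t[None], True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"feature tensor must be (h,w,d) or (N,h,w,d), got {t.shape}")


class SoftAttention(Layer):
    """The attention layer: K spatially-normalized maps, aggregate α, scaled
    branch γ·t⊙α, output concat(t, branch) with 2d channels.

    Parameters
    ----------
    d : channel depth of the incoming feature tensor.
    n_maps : K, the number of attention maps (default 16).
    ksize : spatial extent of the attention convolution (same-padded so the
        maps keep the h×w geometry).
    gamma_init : initial value of the learnable scale γ.
    """

    def __init__(self, d: int, n_maps: int = 16, ksize: int = 3,
                 gamma_init: float = 0.01, rng: np.random.Generator | None = None) -> None:
        if n_maps < 1:
            raise ValueError(f"need at least one attention map, got K={n_maps}")
        self.d = d
        self.n_maps = n_maps
        self.ksize = ksize
        # edge-filled same padding: a constant feature map then scores
        # constant everywhere, so its attention is exactly uniform
        self.conv = Conv2D(d, n_maps, ksize=ksize, padding="same", pad_fill="edge",
                           rng=rng, name="sa.conv")
        self.gamma = Param(np.array(float(gamma_init)), "sa.gamma")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [*self.conv.params(), self.gamma]

    def _check(self, t: np.ndarray) -> None:
        if not np.isfinite(t).all():
            raise ValueError("feature tensor contains non-finite entries")
        if t.shape[1] < self.ksize or t.shape[2] < self.ksize:
            raise ValueError(
                f"spatial dims {t.shape[1:3]} smaller than the {self.ksize}x{self.ksize} attention kernel"
            )

    def attention_maps(self, t: np.ndarray) -> np.ndarray:
        """K softmax-normalized maps, shape (N, h, w, K); each map sums to 1."""
        tb, single = _as_batch(t)
        self._check(tb)
        z = self.conv.forward(tb)  # (N,h,w,K)
        n, h, w, k = z.shape
        zf = z.reshape(n, h * w, k)
        zf = zf - zf.max(axis=1, keepdims=True)
        e = np.exp(zf)
        s = (e / e.sum(axis=1, keepdims=True)).reshape(n, h, w, k)
        return s[0] if single else s

    def forward(self, t: np.ndarray, training: bool = False) -> np.ndarray:
        tb, single = _as_batch(t)
        self._check(tb)
        s = self.attention_maps(tb)          # conv cache is now set for backward
        alpha = s.sum(axis=-1)               # (N,h,w), sums to K over locations
        scaled = self.gamma.value * tb * alpha[..., None]
        self._cache = (tb, s, alpha)
        out = np.concatenate([tb, scaled], axis=-1)
        return out[0] if single else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        tb, s, alpha = self._cache
        single = dout.ndim == 3
        if single:
            dout = dout[None]
        d = self.d
        g1, g2 = dout[..., :d], dout[..., d:]
        gamma = float(self.gamma.value)
        self.gamma.grad += np.sum(g2 * tb * alpha[..., None])
        dt = g1 + gamma * alpha[..., None] * g2
        dalpha = gamma * (g2 * tb).sum(axis=-1)          # (N,h,w)
        ds = np.broadcast_to(dalpha[..., None], s.shape)  # same for every map
        n, h, w, k = s.shape
        sf = s.reshape(n, h * w, k)
        dsf = ds.reshape(n, h * w, k)
        dz = sf * (dsf - (dsf * sf).sum(axis=1, keepdims=True))
        dt = dt + self.conv.backward(dz.reshape(n, h, w, k))
        return dt[0] if single else dt


class SoftAttentionModule(Layer):
    """ReLU → {max-pool, soft-attention → max-pool} → concat → ReLU → dropout.

    Output geometry: spatial dims halved by the pool (default window 2),
    channels d + 2d = 3d.  Dropout (default p = 0.5) is active only in
    training mode, so evaluation-mode output is deterministic.
    """

    def __init__(self, d: int, n_maps: int = 16, ksize: int = 3, pool: int = 2,
                 dropout_p: float = 0.5, gamma_init: float = 0.01,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.attention = SoftAttention(d, n_maps=n_maps, ksize=ksize,
                                       gamma_init=gamma_init, rng=rng)
        self.relu_in = ReLU()
        self.relu_out = ReLU()
        self.pool_plain = MaxPool2D(pool)
        self.pool_attn = MaxPool2D(pool)
        self.dropout = Dropout(dropout_p, rng=rng)
        self.d = d

    def params(self) -> list[Param]:
        return self.attention.params()

    def forward(self, t: np.ndarray, training: bool = False) -> np.ndarray:
        tb, single = _as_batch(t)
        r = self.relu_in.forward(tb)
        p1 = self.pool_plain.forward(r)                       # (N,h',w',d)
        p2 = self.pool_attn.forward(self.attention.forward(r))  # (N,h',w',2d)
        cat = np.concatenate([p1, p2], axis=-1)
        out = self.dropout.forward(self.relu_out.forward(cat), training=training)
        return out[0] if single else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        single = dout.ndim == 3
        if single:
            dout = dout[None]
        dcat = self.relu_out.backward(self.dropout.backward(dout))
        d = self.d
        dr = self.pool_plain.backward(dcat[..., :d])
        dr = dr + self.attention.backward(self.pool_attn.backward(dcat[..., d:]))
        dt = self.relu_in.backward(dr)
        return dt[0] if single else dt


# -- functional views -------------------------------------------------------

def attention_maps(t: np.ndarray, params: SoftAttention) -> np.ndarray:
    """The K spatially softmax-normalized attention maps for ``t``."""
    return params.attention_maps(t)


def attention_aggregate(t: np.ndarray, params: SoftAttention) -> np.ndarray:
    """The aggregate weight field α = Σ_k softmax maps; sums to K."""
    return attention_maps(t, params).sum(axis=-1)


def soft_attention_forward(t: np.ndarray, params: SoftAttention) -> np.ndarray:
    """concat(t, γ·t⊙α) along channels — output has 2d channels."""
    return params.forward(t)


def sa_module_forward(t: np.ndarray, params: SoftAttentionModule,
                      dropout_p: float | None = None, training: bool = False) -> np.ndarray:
    """Full module forward; ``dropout_p`` overrides the module's rate."""
    if dropout_p is not None:
        if not 0.0 <= dropout_p <= 1.0:
            raise ValueError(f"dropout probability must be in [0,1], got {dropout_p}")
        params.dropout.p = dropout_p
    return params.forward(t, training=training)
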