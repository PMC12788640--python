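"""Neural network building blocks on top of the autodiff tape.

Every layer takes an explicit ``numpy.random.Generator`` at construction so
that parameter initialisation — and with it every training trajectory — is
reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Dropout",
    "MLP",
    "SmallConvEncoder",
    "GatedAttention",
    "TransformerEncoderLayer",
]


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=p.data.dtype).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator, pad: int = 1):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(np.float32), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centred * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a no-op unless called with training=True."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None, training: bool = False) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class MLP(Module):
    """Fully connected net with ReLU hidden layers and optional dropout."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int, dropout: float, rng: np.random.Generator):
        dims = [n_in, *hidden]
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.head = Linear(dims[-1], n_out, rng)
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None, training: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
            x = self.dropout(x, rng=rng, training=training)
        return self.head(x)


class SmallConvEncoder(Module):
    """Three stride-2 conv blocks + global average pooling + linear projection.

    Maps (N, 3, H, W) tiles in [0, 1] to (N, d) instance embeddings.  A fixed
    ``input_pool``-fold average pooling precedes the convolutions, keeping the
    net fast enough to train from scratch on a single CPU; a pretrained
    backbone can be plugged in anywhere a callable with the same signature is
    accepted.
    """

    def __init__(
        self,
        d: int,
        rng: np.random.Generator,
        channels: tuple[int, int, int] = (8, 16, 32),
        input_pool: int = 2,
    ):
        c1, c2, c3 = channels
        self.conv1 = Conv2d(3, c1, 3, 2, rng)
        self.conv2 = Conv2d(c1, c2, 3, 2, rng)
        self.conv3 = Conv2d(c2, c3, 3, 2, rng)
        self.proj = Linear(c3, d, rng)
        self.d = d
        self.input_pool = int(input_pool)

    def __call__(self, x: Tensor) -> Tensor:
        p = self.input_pool
        if p > 1:
            n, c, h, w = x.shape
            if h % p or w % p:
                raise ValueError(f"tile size {h}x{w} not divisible by input pool {p}")
            x = x.reshape(n, c, h // p, p, w // p, p).mean(axis=5).mean(axis=3)
        x = x - 0.5  # center the [0, 1] input so first-layer units start balanced
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        n, c = h.shape[0], h.shape[1]
        pooled = h.reshape(n, c, -1).mean(axis=2)  # global average pool
        return self.proj(pooled).relu()


class GatedAttention(Module):
    """Gated attention pooling over a bag of instance embeddings.

    score_k = w^T (tanh(V h_k) * sigmoid(U h_k)); attention weights are the
    softmax of the scores over instances, and the bag embedding is the
    weight-averaged instance embedding.
    """

    def __init__(self, d: int, attention_dim: int, rng: np.random.Generator):
        self.V = Linear(d, attention_dim, rng)
        self.U = Linear(d, attention_dim, rng)
        self.w = Linear(attention_dim, 1, rng)

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: (N, d) -> (weights (N,), bag embedding (1, d))."""
        gate = self.V(h).tanh() * self.U(h).sigmoid()
        scores = self.w(gate).reshape(1, -1)          # (1, N)
        weights = scores.softmax(axis=-1)             # (1, N)
        bag = weights @ h                             # (1, d)
        return weights.reshape(-1), bag


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer (multi-head self-attention + FFN).

    No positional encoding: tile bags are unordered sets, so the layer is
    permutation-equivariant by construction.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2, dropout: float = 0.0):
        if d % n_heads:
            raise ValueError(f"embedding dim {d} not divisible by n_heads {n_heads}")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.out = Linear(d, d, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ff_mult * d, rng)
        self.ff2 = Linear(ff_mult * d, d, rng)
        self.dropout = Dropout(dropout)

    def _attend(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, dk = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(n, 3, h, dk).transpose(1, 2, 0, 3)  # (3, h, N, dk)
        q = qkv.reshape(3 * h, n, dk)
        # split via strided reshape: rows 0..h-1 are q, h..2h-1 k, 2h.. v
        # (slicing is avoided; use three separate matmuls on views)
        q_, k_, v_ = _split3(q, h)
        att = (q_ @ k_.transpose(0, 2, 1)) * (1.0 / np.sqrt(dk))      # (h, N, N)
        att = att.softmax(axis=-1)
        ctx = att @ v_                                                # (h, N, dk)
        ctx = ctx.transpose(1, 0, 2).reshape(n, h * dk)
        return self.out(ctx)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None, training: bool = False) -> Tensor:
        x = x + self.dropout(self._attend(self.norm1(x)), rng=rng, training=training)
        x = x + self.dropout(self.ff2(self.ff1(self.norm2(x)).relu()), rng=rng, training=training)
        return x


def _split3(t: Tensor, h: int) -> tuple[Tensor, Tensor, Tensor]:
    """Split a (3h, N, dk) tensor into three (h, N, dk) tensors along axis 0."""
    parts = []
    for i in range(3):
        sl = slice(i * h, (i + 1) * h)

        def backward(g, sl=sl, shape=t.shape):
            full = np.zeros(shape, dtype=g.dtype)
            full[sl] = g
            return (full,)

        parts.append(Tensor._make(t.data[sl], (t,), backward))
    return tuple(parts)
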