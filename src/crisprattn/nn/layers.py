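"""Neural-network layers built on the autodiff :class:`~crisprattn.nn.tensor.Tensor`.

Initialisation is driven by an explicit ``numpy.random.Generator`` so models are
reproducible from a single integer seed. Layers follow the familiar
module/parameter idiom: ``parameters()`` walks the attribute tree, ``train()`` /
``eval()`` toggle stochastic layers (dropout).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, embedding, max_pool2d

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "PositionalEmbedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "TransformerEncoderLayer",
    "TransformerDecoderLayer",
    "Conv2d",
    "MaxPool2d",
    "LSTM",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def _modules(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters (for checkpointing)."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            a = arrays[f"param_{i}"]
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i}: {a.shape} vs {p.data.shape}")
            p.data = a.astype(np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        s = math.sqrt(6.0 / (in_dim + out_dim))
        self.weight = _param(rng, (in_dim, out_dim), s)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Token-id -> dense vector lookup table."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)), requires_grad=True)

    def forward(self, indices: np.ndarray) -> Tensor:
        return embedding(self.weight, indices)


def sinusoidal_table(max_len: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional table: even columns sine, odd columns cosine."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    table = np.zeros((max_len, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles[:, : dim - dim // 2])
    return table


class PositionalEmbedding(Module):
    """Per-position vector added elementwise to the token embedding matrix.

    ``mode='learned'`` (default) trains the table; ``mode='sinusoidal'`` uses the
    fixed closed form.
    """

    def __init__(self, max_len: int, dim: int, rng: np.random.Generator, mode: str = "learned"):
        super().__init__()
        if mode == "learned":
            self.table = Tensor(rng.normal(0.0, 0.1, size=(max_len, dim)), requires_grad=True)
        elif mode == "sinusoidal":
            self.table = Tensor(sinusoidal_table(max_len, dim))
        else:
            raise ValueError(f"unknown positional embedding mode: {mode!r}")
        self.mode = mode

    def forward(self, x: Tensor) -> Tensor:
        length = x.shape[-2]
        return x + self.table[:length]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.shift


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention (self- or cross-attention)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        return x.reshape(b, l, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, memory: Tensor | None = None) -> Tensor:
        mem = x if memory is None else memory
        b, l, d = x.shape
        q = self._split(self.q(x))  # (B, H, L, dh)
        k = self._split(self.k(mem))
        v = self._split(self.v(mem))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (B, H, L, dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and a position-wise feed-forward,
    each wrapped in residual + layer norm. Output shape equals input shape."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(x + self.drop(self.attn(x)))
        z = self.norm2(y + self.drop(self.ff2(self.ff1(y).relu())))
        assert z.shape == x.shape, "transformer block must preserve input shape"
        return z


class TransformerDecoderLayer(Module):
    """Decoder block: self-attention over the target sequence, then cross-attention
    against the encoder output, then feed-forward; post-norm residuals throughout."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor, memory: Tensor) -> Tensor:
        y = self.norm1(x + self.drop(self.self_attn(x)))
        z = self.norm2(y + self.drop(self.cross_attn(y, memory=memory)))
        w = self.norm3(z + self.drop(self.ff2(self.ff1(z).relu())))
        assert w.shape == x.shape
        return w


class Conv2d(Module):
    """Valid (no padding) 2-d convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        s = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, s, size=(out_ch, in_ch, kh, kw)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel: tuple[int, int]):
        super().__init__()
        self.kernel = tuple(kernel)

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, *self.kernel)


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state (B, hidden)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        s = math.sqrt(6.0 / (in_dim + hidden))
        self.w_ih = _param(rng, (in_dim, 4 * hidden), s)
        self.w_hh = _param(rng, (hidden, 4 * hidden), s)
        self.bias = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.hidden = hidden

    def forward(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        h = Tensor(np.zeros((b, self.hidden)))
        c = Tensor(np.zeros((b, self.hidden)))
        nh = self.hidden
        for t in range(length):
            xt = x[:, t, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, :nh].sigmoid()
            f = gates[:, nh : 2 * nh].sigmoid()
            g = gates[:, 2 * nh : 3 * nh].tanh()
            o = gates[:, 3 * nh :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h
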