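"""Neural-network building blocks on top of the autodiff engine.

Pre-norm transformer encoder/decoder layers with multi-head attention,
sized for short peptide sequences (frame length L_max + 2) and CPU
training.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concatenate, embedding_lookup

NEG_INF = -1e9  # additive attention mask value


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(1.0 / in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(num_embeddings, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class MLP(Module):
    """Stack of Linear layers with a nonlinearity between them."""

    def __init__(self, dims: list[int], rng: np.random.Generator, activation: str = "gelu"):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = getattr(x, self.activation)()
        return x


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).swapaxes(1, 2)  # (B, H, T, dh)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, t, dh = x.shape
    return x.swapaxes(1, 2).reshape(b, t, h * dh)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.scale = 1.0 / np.sqrt(dim // n_heads)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 attn_mask: np.ndarray | None = None) -> Tensor:
        """attn_mask: additive float array broadcastable to (B, H, Tq, Tk)."""
        q = _split_heads(self.q_proj(query), self.n_heads)
        k = _split_heads(self.k_proj(key), self.n_heads)
        v = _split_heads(self.v_proj(value), self.n_heads)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale
        if attn_mask is not None:
            scores = scores + Tensor(attn_mask)
        weights = scores.softmax(axis=-1)
        out = weights @ v
        return self.out_proj(_merge_heads(out))


class TransformerEncoderLayer(Module):
    """Pre-norm self-attention block."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h, attn_mask=attn_mask)
        h = self.norm2(x)
        return x + self.ff2(self.ff1(h).gelu())


class TransformerDecoderLayer(Module):
    """Pre-norm causal self-attention + cross-attention block."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor, memory: Tensor,
                 self_mask: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        x = x + self.self_attn(h, h, h, attn_mask=self_mask)
        h = self.norm2(x)
        x = x + self.cross_attn(h, memory, memory)
        h = self.norm3(x)
        return x + self.ff2(self.ff1(h).gelu())


def sinusoidal_positions(n_positions: int, dim: int) -> np.ndarray:
    """Classic fixed sinusoidal positional encoding table."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.zeros((n_positions, dim))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


def causal_mask(t: int) -> np.ndarray:
    """Additive (t, t) mask forbidding attention to future positions."""
    mask = np.zeros((t, t))
    mask[np.triu_indices(t, k=1)] = NEG_INF
    return mask


def padding_attn_mask(pad: np.ndarray) -> np.ndarray:
    """Additive mask hiding padded key positions; pad is (B, T) bool."""
    mask = np.zeros((pad.shape[0], 1, 1, pad.shape[1]))
    mask[:, 0, 0, :][pad] = NEG_INF
    return mask


def masked_mean(x: Tensor, keep: np.ndarray) -> Tensor:
    """Mean of x (B, T, D) over positions where keep (B, T) is True."""
    w = keep.astype(np.float64)
    denom = w.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("masked_mean: some rows have no kept positions")
    weights = w / denom  # (B, T)
    return (x * Tensor(weights[:, :, None])).sum(axis=1)
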