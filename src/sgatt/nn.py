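"""Neural-network layers and optimisation built on :mod:`sgatt.autodiff`.

Initialisation takes an explicit ``numpy.random.Generator`` so whole-model
construction is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concatenate, sigmoid, softmax, tanh, where_mask


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny Module base: recursive parameter discovery plus train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _collect(value, seen)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        seen: set[int] = set()
        for name, value in self.__dict__.items():
            yield from _collect_named(name, value, seen)

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield from v.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value, seen):
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for v in value.__dict__.values():
            yield from _collect(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v, seen)


def _collect_named(prefix, value, seen):
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield prefix, value
    elif isinstance(value, Module):
        for name, v in value.__dict__.items():
            yield from _collect_named(f"{prefix}.{name}", v, seen)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(f"{prefix}.{i}", v, seen)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(xavier_uniform(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(num_embeddings, dim)))

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; draws from a module-local generator for replayability."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float64)
        return x * Tensor(keep / (1.0 - self.p))


class GRUCell(Module):
    """Gated recurrent cell: state update h' = (1-z)*n + z*h."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w_ih = Parameter(xavier_uniform(rng, input_dim, 3 * hidden_dim))
        self.w_hh = Parameter(xavier_uniform(rng, hidden_dim, 3 * hidden_dim))
        self.b_ih = Parameter(np.zeros(3 * hidden_dim))
        self.b_hh = Parameter(np.zeros(3 * hidden_dim))
        self.hidden_dim = hidden_dim

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_dim
        gi = x @ self.w_ih + self.b_ih
        gh = h @ self.w_hh + self.b_hh
        r = sigmoid(gi[..., :H] + gh[..., :H])
        z = sigmoid(gi[..., H : 2 * H] + gh[..., H : 2 * H])
        n = tanh(gi[..., 2 * H :] + r * gh[..., 2 * H :])
        return (1.0 - z) * n + z * h


class LSTMCell(Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w_ih = Parameter(xavier_uniform(rng, input_dim, 4 * hidden_dim))
        self.w_hh = Parameter(xavier_uniform(rng, hidden_dim, 4 * hidden_dim))
        self.b = Parameter(np.zeros(4 * hidden_dim))
        self.hidden_dim = hidden_dim

    def forward(self, x: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, Tensor]:
        h, c = state
        H = self.hidden_dim
        g = x @ self.w_ih + h @ self.w_hh + self.b
        i = sigmoid(g[..., :H])
        f = sigmoid(g[..., H : 2 * H])
        o = sigmoid(g[..., 2 * H : 3 * H])
        u = tanh(g[..., 3 * H :])
        c_new = f * c + i * u
        h_new = o * tanh(c_new)
        return h_new, c_new


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        from .autodiff import gelu

        self.lin1 = Linear(dim, hidden, rng)
        self.lin2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)
        self._act = gelu

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.lin2(self._act(self.lin1(x))))


class MultiHeadSelfAttention(Module):
    """Self-attention over padded batches (B, L, C) with a key-padding mask."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        self.last_weights: np.ndarray | None = None

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, L, _ = x.shape
        h, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, L, C) -> (B, h, L, hd)
            return t.reshape(B, L, h, hd).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.T) * (1.0 / np.sqrt(hd))  # (B, h, L, L)
        key_mask = np.broadcast_to(pad_mask[:, None, None, :], scores.shape)
        scores = where_mask(key_mask, scores, -1e30)
        attn = softmax(scores, axis=-1)
        self.last_weights = attn.data
        out = (self.drop(attn) @ v).swapaxes(1, 2).reshape(B, L, self.dim)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-LN block: x + MHSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, dim: int, heads: int, ff_hidden: int, rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng, dropout)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_hidden, rng, dropout)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x), pad_mask))
        x = x + self.ff(self.ln2(x))
        return x


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
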