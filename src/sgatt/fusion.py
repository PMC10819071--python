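"""Cross-attention fusion of sequence and graph features, decoding, losses.

Queries come from the sequence encoder's token states; keys and values are
affine projections of the graph embedding, treated as a one-element memory
(scaled multi-head attention, scale √(C/d) with C the embedding dimension
and d the number of heads). Attended states are added back to the token
states (residual) and mean-pooled into the fused vector consumed by a
three-layer feed-forward decoder. The residual is required for end-to-end
training: with a one-element memory the softmax weights are constant, so
without it no gradient would reach the sequence branch.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .autodiff import Tensor, relu, sigmoid, softmax, where_mask

logger = logging.getLogger(__name__)

#: clamp for classification probabilities entering the log
EPS = 1e-7


class CrossAttention(nn.Module):
    def __init__(self, dim: int = 128, heads: int = 8, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.wv = nn.Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None

    def attend(self, seq_states: Tensor, graph_vec: Tensor) -> Tensor:
        """Pure scaled attention Softmax(QKᵀ/√(C/d))·V per token → (B, L, C).

        ``graph_vec`` may be (B, C) — promoted to a one-element memory.
        """
        if graph_vec.ndim == 2:
            graph_vec = graph_vec.reshape(graph_vec.shape[0], 1, graph_vec.shape[1])
        B, L, C = seq_states.shape
        if C != self.dim or graph_vec.shape[-1] != self.dim:
            raise ValueError(
                f"dimension mismatch: got seq {C}, graph {graph_vec.shape[-1]}, expected {self.dim}"
            )
        M = graph_vec.shape[1]
        h, hd = self.heads, self.head_dim

        q = self.wq(seq_states).reshape(B, L, h, hd).swapaxes(1, 2)  # (B, h, L, hd)
        k = self.wk(graph_vec).reshape(B, M, h, hd).swapaxes(1, 2)  # (B, h, M, hd)
        v = self.wv(graph_vec).reshape(B, M, h, hd).swapaxes(1, 2)
        scores = (q @ k.T) * (1.0 / np.sqrt(C / h))  # (B, h, L, M)
        attn = softmax(scores, axis=-1)
        self.last_weights = attn.data
        return (attn @ v).swapaxes(1, 2).reshape(B, L, C)

    def forward(self, seq_states: Tensor, graph_vec: Tensor, seq_mask: np.ndarray) -> Tensor:
        """Fuse token states with the graph memory → (B, C) fused vector."""
        out = seq_states + self.attend(seq_states, graph_vec)
        m = Tensor(seq_mask.astype(np.float64)[..., None])
        counts = Tensor(seq_mask.sum(axis=1, keepdims=True).astype(np.float64))
        return (out * m).sum(axis=1) / counts


class Decoder(nn.Module):
    """Three-layer feed-forward decoder with per-task output heads."""

    def __init__(
        self,
        in_dim: int,
        n_tasks: int,
        hidden: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = hidden or in_dim
        self.lin1 = nn.Linear(in_dim, hidden, rng)
        self.lin2 = nn.Linear(hidden, hidden, rng)
        self.lin3 = nn.Linear(hidden, n_tasks, rng)
        self.n_tasks = n_tasks

    def forward(self, fused: Tensor) -> Tensor:
        return self.lin3(relu(self.lin2(relu(self.lin1(fused)))))


def decode(fused: Tensor, decoder: Decoder, task_type: str = "classification") -> Tensor:
    """Decode fused embeddings to predictions.

    Classification outputs pass a sigmoid (per-task probabilities in
    (0, 1)); regression outputs stay unbounded.
    """
    logits = decoder(fused)
    if task_type == "classification":
        return sigmoid(logits)
    return logits


def loss_classification(y: np.ndarray, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Masked mean binary cross-entropy −[y ln x + (1−y) ln(1−x)].

    Predictions are clamped to [EPS, 1−EPS]; masked entries never enter
    the loss. A fully masked batch yields zero loss with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(y, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        logger.warning("classification loss over a fully masked batch; returning 0")
        return Tensor(0.0)
    xc = where_mask(x.data >= EPS, x, EPS)
    xc = where_mask(xc.data <= 1.0 - EPS, xc, 1.0 - EPS)
    term = Tensor(y) * xc.log() + Tensor(1.0 - y) * (1.0 - xc).log()
    masked = where_mask(mask, term, 0.0)
    return -masked.sum() / n


def loss_regression(y: np.ndarray, x: Tensor) -> Tensor:
    """Root-mean-square error √((1/m) Σ (y − x)²)."""
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("regression loss needs at least one target")
    diff = Tensor(y) - x
    return ((diff * diff).sum() / y.size).sqrt()
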