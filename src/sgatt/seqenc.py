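"""Transformer encoder over FCS token sequences.

Token embedding + learned positional embedding feed a stack of
multi-head self-attention blocks; the pooled vector is the mean of the
contextual states over real (non-pad) positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .autodiff import Tensor, segment_sum
from .fcs import FCSVocabulary, TokenSequence

logger = logging.getLogger(__name__)


@dataclass
class SequenceEncoding:
    """Contextual token states (q × model_dim) and the pooled vector T1."""

    token_states: np.ndarray
    pooled: np.ndarray


class SequenceEncoder(nn.Module):
    """Self-attention encoder mapping token-id sequences to contextual states.

    Parameters mirror the reference configuration: 8 attention heads and a
    128-dimensional feature length by default; layer count, feed-forward
    width and dropout are conventional encoder defaults.
    """

    def __init__(
        self,
        vocab: FCSVocabulary | dict[str, int],
        model_dim: int = 128,
        heads: int = 8,
        num_layers: int = 4,
        max_len: int = 256,
        dropout: float = 0.1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.token_index = vocab.index() if isinstance(vocab, FCSVocabulary) else dict(vocab)
        self.model_dim = model_dim
        self.max_len = max_len
        self.token_emb = nn.Embedding(len(self.token_index), model_dim, rng)
        self.pos_emb = nn.Embedding(max_len, model_dim, rng)
        self.layers = [
            nn.TransformerEncoderLayer(model_dim, heads, 4 * model_dim, rng, dropout)
            for _ in range(num_layers)
        ]
        self.final_ln = nn.LayerNorm(model_dim)

    def encode_ids(self, sequences: Sequence[TokenSequence | Sequence[str]]) -> list[np.ndarray]:
        """Map token sequences to id arrays, truncating past ``max_len``."""
        out = []
        for seq in sequences:
            toks = list(seq)
            if len(toks) > self.max_len:
                logger.warning("sequence of %d tokens truncated to %d", len(toks), self.max_len)
                toks = toks[: self.max_len]
            try:
                out.append(np.array([self.token_index[t] for t in toks], dtype=np.int64))
            except KeyError as exc:
                raise KeyError(f"token {exc.args[0]!r} missing from the encoder vocabulary") from exc
        return out

    def forward(
        self, sequences: Sequence[TokenSequence | Sequence[str]]
    ) -> tuple[Tensor, np.ndarray, Tensor]:
        """Encode a batch.

        Returns ``(token_states, mask, pooled)`` where token_states is
        (B, L, C), mask is a boolean (B, L) array flagging real positions,
        and pooled is (B, C) — mean over non-pad positions.
        """
        ids = self.encode_ids(sequences)
        if any(len(a) == 0 for a in ids):
            raise ValueError("cannot encode an empty token sequence")
        B = len(ids)
        L = max(len(a) for a in ids)
        id_mat = np.zeros((B, L), dtype=np.int64)
        mask = np.zeros((B, L), dtype=bool)
        for b, a in enumerate(ids):
            id_mat[b, : len(a)] = a
            mask[b, : len(a)] = True

        pos = np.broadcast_to(np.arange(L), (B, L))
        x = self.token_emb(id_mat) + self.pos_emb(pos)
        for layer in self.layers:
            x = layer(x, mask)
        x = self.final_ln(x)

        m = Tensor(mask.astype(np.float64)[..., None])
        counts = Tensor(mask.sum(axis=1, keepdims=True).astype(np.float64))
        pooled = (x * m).sum(axis=1) / counts
        return x, mask, pooled


def encode_sequence(tokens: TokenSequence, encoder: SequenceEncoder) -> SequenceEncoding:
    """Encode a single token sequence into contextual states and pooled T1."""
    states, mask, pooled = encoder([tokens])
    q = int(mask[0].sum())
    return SequenceEncoding(token_states=states.data[0, :q], pooled=pooled.data[0])
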