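"""Full sequence–graph cross-attention model and molecule featurisation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .ampnn import GraphBatch, GraphEncoder, label_vocabulary
from .autodiff import Tensor
from .fcs import FCSVocabulary, TokenSequence, tokenize
from .fusion import CrossAttention, Decoder, sigmoid
from .knowledge import AugmentedGraph, KnowledgeBase, augment_graph
from .molio import parse_smiles
from .seqenc import SequenceEncoder

ABLATIONS = ("full", "no_graph", "no_sequence")


class MoleculeFeaturizer:
    """Caches per-SMILES token sequences and augmented graphs.

    Hydrogens are made explicit iff some functional-group pattern needs
    them (override with ``explicit_h``); the raw input SMILES — not a
    canonical form — feeds the tokenizer.
    """

    def __init__(
        self,
        vocab: FCSVocabulary,
        kb: KnowledgeBase,
        explicit_h: bool | None = None,
    ):
        self.vocab = vocab
        self.kb = kb
        self.explicit_h = (
            explicit_h
            if explicit_h is not None
            else any(fg.include_h for fg in kb.functional_groups)
        )
        self._cache: dict[str, tuple[TokenSequence, AugmentedGraph]] = {}

    def featurize(self, smiles: str) -> tuple[TokenSequence, AugmentedGraph]:
        hit = self._cache.get(smiles)
        if hit is None:
            tokens = tokenize(smiles, self.vocab)
            graph = augment_graph(parse_smiles(smiles, add_hydrogens=self.explicit_h), self.kb)
            hit = (tokens, graph)
            self._cache[smiles] = hit
        return hit

    def featurize_batch(
        self, smiles: Sequence[str]
    ) -> tuple[list[TokenSequence], list[AugmentedGraph]]:
        pairs = [self.featurize(s) for s in smiles]
        return [p[0] for p in pairs], [p[1] for p in pairs]


@dataclass
class ModelConfig:
    dim: int = 128
    seq_heads: int = 8
    seq_layers: int = 4
    fusion_heads: int = 8
    rounds: int = 3
    aggregation: str = "sum"
    set2set_steps: int = 3
    max_len: int = 256
    dropout: float = 0.1
    decoder_hidden: int | None = None
    ablation: str = "full"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")


class SGATT(nn.Module):
    """Sequence encoder + knowledge-graph encoder fused by cross-attention.

    ``ablation="no_graph"`` routes the pooled sequence vector straight to
    the decoder; ``"no_sequence"`` routes the graph embedding. The decoder
    is identical in every mode.
    """

    def __init__(
        self,
        vocab: FCSVocabulary,
        kb: KnowledgeBase,
        n_tasks: int,
        task_type: str = "classification",
        config: ModelConfig | None = None,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        cfg = config or ModelConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = cfg
        self.task_type = task_type
        self.n_tasks = n_tasks
        self.label_index = label_vocabulary(kb)
        self.seq_encoder = SequenceEncoder(
            vocab,
            model_dim=cfg.dim,
            heads=cfg.seq_heads,
            num_layers=cfg.seq_layers,
            max_len=cfg.max_len,
            dropout=cfg.dropout,
            rng=rng,
        )
        self.graph_encoder = GraphEncoder(
            self.label_index,
            dim=cfg.dim,
            rounds=cfg.rounds,
            aggregation=cfg.aggregation,
            set2set_steps=cfg.set2set_steps,
            rng=rng,
        )
        self.cross_attention = CrossAttention(cfg.dim, cfg.fusion_heads, rng)
        self.decoder = Decoder(cfg.dim, n_tasks, cfg.decoder_hidden, rng)

    # -- embedding -------------------------------------------------------------
    def fuse(
        self, tokens: Sequence[TokenSequence], graphs: Sequence[AugmentedGraph] | GraphBatch
    ) -> Tensor:
        """Produce the fused (B, dim) embedding according to the ablation mode."""
        mode = self.config.ablation
        if mode == "no_graph":
            _, _, pooled = self.seq_encoder(tokens)
            return pooled
        graph_vec = self.graph_encoder(graphs)
        if mode == "no_sequence":
            return graph_vec
        states, mask, _ = self.seq_encoder(tokens)
        return self.cross_attention(states, graph_vec, mask)

    def forward(
        self, tokens: Sequence[TokenSequence], graphs: Sequence[AugmentedGraph] | GraphBatch
    ) -> Tensor:
        """Per-task predictions: probabilities (classification) or raw values."""
        logits = self.decoder(self.fuse(tokens, graphs))
        if self.task_type == "classification":
            return sigmoid(logits)
        return logits

    def predict_smiles(self, smiles: Sequence[str], featurizer: MoleculeFeaturizer) -> np.ndarray:
        from .autodiff import no_grad

        self.eval()
        toks, graphs = featurizer.featurize_batch(smiles)
        with no_grad():
            return self.forward(toks, graphs).data
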