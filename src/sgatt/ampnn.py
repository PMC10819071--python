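"""Attention message passing over knowledge-augmented molecular graphs.

Two message channels run per round: channel 1 carries knowledge
(property/functional-group virtual node → atom) edges, channel 2 carries
atom–atom bond edges. Each channel scores its incoming edges with
GAT-style coefficients — LeakyReLU(aᵀ[Wh_u ‖ Wh_v]) softmax-normalised
over the receiver's channel neighbourhood — and emits per-edge messages

    m_uv = σ(α_uv · W_c he_uv) ⊙ h_u

(a gated transform of the static edge state, modulated elementwise by the
sender state). Channel aggregates are summed (or averaged) per receiver
and fed to a GRU cell as input, with the previous node state as state.
After K rounds a Set2Set pooling over atom states (virtual nodes
excluded) yields the graph embedding, projected back to the model width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .autodiff import (
    Tensor,
    concatenate,
    leaky_relu,
    segment_sum,
    sigmoid,
)
from .knowledge import (
    FUNCTIONAL_GROUP_RELATION,
    AugmentedGraph,
    KnowledgeBase,
    RELATION_NAMES,
)
from .molio import ATOM_FEATURE_DIM, BOND_FEATURE_DIM

#: fixed relation vocabulary: five property relations + the substructure relation
RELATION_INDEX: dict[str, int] = {
    **{rel: i for i, rel in enumerate(RELATION_NAMES.values())},
    FUNCTIONAL_GROUP_RELATION: len(RELATION_NAMES),
}


def label_vocabulary(kb: KnowledgeBase) -> dict[str, int]:
    """Stable label → id map over property labels and functional-group names."""
    labels = list(kb.property_labels) + sorted({fg.name for fg in kb.functional_groups})
    return {lab: i for i, lab in enumerate(labels)}


@dataclass
class GraphBatch:
    """Flattened node/edge tables for a batch of augmented graphs.

    Nodes of all graphs are laid out contiguously: the atoms of graph g
    first, then its virtual nodes, then graph g+1. ``atom_rows`` /
    ``virt_rows`` index back into that layout.
    """

    atom_features: np.ndarray  # (N_atom, ATOM_FEATURE_DIM)
    virt_labels: np.ndarray  # (N_virt,) label ids
    atom_rows: np.ndarray  # (N_atom,) node indices of atoms
    virt_rows: np.ndarray  # (N_virt,) node indices of virtual nodes
    num_nodes: int
    # channel 1: knowledge edges (virtual -> atom)
    know_src: np.ndarray
    know_dst: np.ndarray
    know_rel: np.ndarray  # relation ids
    # channel 2: bond edges (atom -> atom, both directions present)
    bond_src: np.ndarray
    bond_dst: np.ndarray
    bond_features: np.ndarray  # (E_bond, BOND_FEATURE_DIM)
    atom_graph_ids: np.ndarray  # (N_atom,) graph id per atom
    num_graphs: int

    @classmethod
    def from_graphs(
        cls, graphs: Sequence[AugmentedGraph], label_index: dict[str, int]
    ) -> "GraphBatch":
        atom_feats, virt_labels = [], []
        atom_rows, virt_rows, atom_gids = [], [], []
        ks, kd, kr = [], [], []
        bs, bd, bf = [], [], []
        offset = 0
        for gid, ag in enumerate(graphs):
            n_atoms = ag.base.num_atoms
            for node in ag.base.nodes:
                atom_feats.append(node.features)
                atom_rows.append(offset + node.index)
                atom_gids.append(gid)
            for v in ag.virtual_nodes:
                try:
                    virt_labels.append(label_index[v.label])
                except KeyError:
                    raise KeyError(f"virtual-node label {v.label!r} missing from label index")
                virt_rows.append(offset + v.id)
            for e in ag.virtual_edges:
                ks.append(offset + e.source)
                kd.append(offset + e.target)
                kr.append(RELATION_INDEX[e.relation])
            for e in ag.base.edges:
                bs.append(offset + e.i)
                bd.append(offset + e.j)
                bf.append(e.features)
            offset += n_atoms + len(ag.virtual_nodes)

        def arr(x, dtype=np.int64):
            return np.asarray(x, dtype=dtype)

        return cls(
            atom_features=np.stack(atom_feats) if atom_feats else np.zeros((0, ATOM_FEATURE_DIM)),
            virt_labels=arr(virt_labels),
            atom_rows=arr(atom_rows),
            virt_rows=arr(virt_rows),
            num_nodes=offset,
            know_src=arr(ks),
            know_dst=arr(kd),
            know_rel=arr(kr),
            bond_src=arr(bs),
            bond_dst=arr(bd),
            bond_features=np.stack(bf) if bf else np.zeros((0, BOND_FEATURE_DIM)),
            atom_graph_ids=arr(atom_gids),
            num_graphs=len(graphs),
        )


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of `scores` within each segment (receiver neighbourhood)."""
    seg = np.asarray(segment_ids, dtype=np.int64)
    if len(seg) == 0:
        return scores
    # per-segment max as a constant shift for numerical stability
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, seg, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    z = (scores - Tensor(seg_max[seg])).exp()
    denom = segment_sum(z, seg, num_segments)
    return z / denom[seg]


class _Channel(nn.Module):
    """One attention message-passing channel (shared across rounds)."""

    def __init__(self, dim: int, rng: np.random.Generator, leaky_slope: float = 0.2):
        super().__init__()
        self.w_att = nn.Linear(dim, dim, rng, bias=False)  # W of the score
        self.a_src = nn.Parameter(nn.xavier_uniform(rng, dim, 1, shape=(dim,)))
        self.a_dst = nn.Parameter(nn.xavier_uniform(rng, dim, 1, shape=(dim,)))
        self.w_edge = nn.Linear(dim, dim, rng, bias=False)  # W_c of the message
        self.slope = leaky_slope

    def attention(
        self, h: Tensor, src: np.ndarray, dst: np.ndarray, num_nodes: int
    ) -> Tensor:
        wh = self.w_att(h)
        s_src = wh @ self.a_src  # (N,)
        s_dst = wh @ self.a_dst
        scores = leaky_relu(s_src[src] + s_dst[dst], self.slope)
        return segment_softmax(scores, dst, num_nodes)

    def messages(
        self, h: Tensor, edge_state: Tensor, src: np.ndarray, dst: np.ndarray, num_nodes: int
    ) -> Tensor:
        alpha = self.attention(h, src, dst, num_nodes)
        gate = sigmoid(alpha.reshape(-1, 1) * self.w_edge(edge_state))
        return gate * h[src]


class GraphEncoder(nn.Module):
    """Dual-channel attention MPNN over augmented molecular graphs.

    Parameters
    ----------
    label_index
        Virtual-node label → id map (see :func:`label_vocabulary`).
    dim
        Node/edge hidden width F.
    rounds
        Message-passing rounds K (small by design, default 3).
    aggregation
        Per-receiver channel aggregation: "sum" or "mean".
    set2set_steps
        Processing steps T of the Set2Set readout.
    """

    def __init__(
        self,
        label_index: dict[str, int],
        dim: int = 128,
        rounds: int = 3,
        aggregation: str = "sum",
        set2set_steps: int = 3,
        leaky_slope: float = 0.2,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if aggregation not in ("sum", "mean"):
            raise ValueError(f"aggregation must be 'sum' or 'mean', got {aggregation!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.rounds = rounds
        self.aggregation = aggregation
        self.set2set_steps = set2set_steps
        self.label_index = dict(label_index)

        self.atom_proj = nn.Linear(ATOM_FEATURE_DIM, dim, rng)
        self.label_emb = nn.Embedding(max(len(label_index), 1), dim, rng)
        self.bond_proj = nn.Linear(BOND_FEATURE_DIM, dim, rng)
        self.rel_emb = nn.Embedding(len(RELATION_INDEX), dim, rng)
        self.know_channel = _Channel(dim, rng, leaky_slope)
        self.bond_channel = _Channel(dim, rng, leaky_slope)
        self.gru = nn.GRUCell(dim, dim, rng)
        self.s2s_lstm = nn.LSTMCell(2 * dim, dim, rng)
        self.out_proj = nn.Linear(2 * dim, dim, rng)

    # -- initial states --------------------------------------------------------
    def initial_node_states(self, batch: GraphBatch) -> Tensor:
        parts, rows = [], []
        if len(batch.atom_rows):
            parts.append(self.atom_proj(Tensor(batch.atom_features)))
            rows.append(batch.atom_rows)
        if len(batch.virt_rows):
            parts.append(self.label_emb(batch.virt_labels))
            rows.append(batch.virt_rows)
        stacked = concatenate(parts, axis=0)
        order = np.concatenate(rows)
        perm = np.empty(batch.num_nodes, dtype=np.int64)
        perm[order] = np.arange(batch.num_nodes)
        return stacked[perm]

    def _aggregate(self, msgs: Tensor, dst: np.ndarray, num_nodes: int) -> Tensor:
        agg = segment_sum(msgs, dst, num_nodes)
        if self.aggregation == "mean":
            deg = np.zeros(num_nodes)
            np.add.at(deg, dst, 1.0)
            agg = agg * Tensor(1.0 / np.maximum(deg, 1.0)[:, None])
        return agg

    # -- message passing -------------------------------------------------------
    def message_pass(self, batch: GraphBatch) -> Tensor:
        """Run K rounds; returns final node states (num_nodes, F)."""
        h = self.initial_node_states(batch)
        know_edge = (
            self.rel_emb(batch.know_rel) if len(batch.know_src) else None
        )
        bond_edge = (
            self.bond_proj(Tensor(batch.bond_features)) if len(batch.bond_src) else None
        )
        n = batch.num_nodes
        for _ in range(self.rounds):
            total = None
            if know_edge is not None:
                m1 = self.know_channel.messages(h, know_edge, batch.know_src, batch.know_dst, n)
                total = self._aggregate(m1, batch.know_dst, n)
            if bond_edge is not None:
                m2 = self.bond_channel.messages(h, bond_edge, batch.bond_src, batch.bond_dst, n)
                agg2 = self._aggregate(m2, batch.bond_dst, n)
                total = agg2 if total is None else total + agg2
            if total is None:
                total = Tensor(np.zeros((n, self.dim)))
            h = self.gru(total, h)
        return h

    # -- readout ---------------------------------------------------------------
    def readout(self, states: Tensor, batch: GraphBatch) -> Tensor:
        """Set2Set pooling of final atom states into one vector per graph."""
        h_atoms = states[batch.atom_rows]
        gids = batch.atom_graph_ids
        B, F = batch.num_graphs, self.dim
        q_star = Tensor(np.zeros((B, 2 * F)))
        hl = Tensor(np.zeros((B, F)))
        cl = Tensor(np.zeros((B, F)))
        for _ in range(self.set2set_steps):
            hl, cl = self.s2s_lstm(q_star, (hl, cl))
            energy = (h_atoms * hl[gids]).sum(axis=-1)
            attn = segment_softmax(energy, gids, B)
            read = segment_sum(attn.reshape(-1, 1) * h_atoms, gids, B)
            q_star = concatenate([hl, read], axis=-1)
        return self.out_proj(q_star)

    def forward(self, graphs: Sequence[AugmentedGraph] | GraphBatch) -> Tensor:
        """Encode augmented graphs to (B, F) embeddings."""
        batch = (
            graphs
            if isinstance(graphs, GraphBatch)
            else GraphBatch.from_graphs(graphs, self.label_index)
        )
        states = self.message_pass(batch)
        return self.readout(states, batch)


def attention_coefficients(
    h_receiver: np.ndarray,
    h_neighbors: np.ndarray,
    W: np.ndarray,
    a: np.ndarray,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Stand-alone GAT-style coefficients for one receiver's neighbourhood.

    score(u, v) = LeakyReLU(aᵀ[W h_u ‖ W h_v]); returns the softmax over
    the given neighbours (senders u, receiver v).
    """
    h_neighbors = np.atleast_2d(np.asarray(h_neighbors, dtype=np.float64))
    if h_neighbors.shape[0] == 0:
        return np.zeros(0)
    wu = h_neighbors @ W.T
    wv = np.asarray(W, dtype=np.float64) @ np.asarray(h_receiver, dtype=np.float64)
    F = wv.shape[0]
    scores = wu @ a[:F] + wv @ a[F:]
    scores = np.where(scores > 0, scores, leaky_slope * scores)
    scores -= scores.max()
    e = np.exp(scores)
    return e / e.sum()
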