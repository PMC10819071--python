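"""Graph-encoder tests, including independent brute-force oracles.

The oracles re-derive every quantity from the documented equations with
plain per-node NumPy loops, reading weights off the encoder modules but
never calling its vectorised code paths.
"""

import numpy as np
import pytest

from sgatt.ampnn import (
    GraphBatch,
    GraphEncoder,
    attention_coefficients,
    label_vocabulary,
    segment_softmax,
)
from sgatt.autodiff import Tensor
from sgatt.knowledge import AugmentedGraph, augment_graph
from sgatt.molio import parse_smiles


def bare(graph):
    """Augmented graph with zero virtual nodes (knowledge channel empty)."""
    return AugmentedGraph(base=graph, virtual_nodes=[], virtual_edges=[])


def make_encoder(kb, dim=4, rounds=1, seed=0, **kw):
    return GraphEncoder(label_vocabulary(kb), dim=dim, rounds=rounds,
                        rng=np.random.default_rng(seed), **kw)


# ---------------------------------------------------------------------------
# oracle pieces (independent re-derivations)
# ---------------------------------------------------------------------------

def oracle_softmax_scores(scores):
    e = np.exp(scores - scores.max())
    return e / e.sum()


def oracle_gru(x, h, cell):
    H = cell.hidden_dim
    gi = x @ cell.w_ih.data + cell.b_ih.data
    gh = h @ cell.w_hh.data + cell.b_hh.data
    sig = lambda v: 1 / (1 + np.exp(-v))
    r = sig(gi[:H] + gh[:H])
    z = sig(gi[H:2 * H] + gh[H:2 * H])
    n = np.tanh(gi[2 * H:] + r * gh[2 * H:])
    return (1 - z) * n + z * h


def oracle_lstm(x, h, c, cell):
    H = cell.hidden_dim
    g = x @ cell.w_ih.data + h @ cell.w_hh.data + cell.b.data
    sig = lambda v: 1 / (1 + np.exp(-v))
    i, f, o, u = g[:H], g[H:2 * H], g[2 * H:3 * H], g[3 * H:]
    c_new = sig(f) * c + sig(i) * np.tanh(u)
    return sig(o) * np.tanh(c_new), c_new


class TestAttentionCoefficients:
    def test_single_neighbor_weight_one(self, rng):
        W = rng.normal(size=(4, 4))
        a = rng.normal(size=8)
        w = attention_coefficients(rng.normal(size=4), rng.normal(size=(1, 4)), W, a)
        np.testing.assert_allclose(w, [1.0])

    def test_identical_neighbors_split_evenly(self, rng):
        W = rng.normal(size=(4, 4))
        a = rng.normal(size=8)
        nbr = rng.normal(size=4)
        w = attention_coefficients(rng.normal(size=4), np.stack([nbr, nbr]), W, a)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_three_neighbors_match_bruteforce(self, rng):
        # oracle: direct evaluation of score = LeakyReLU(a^T [Wh_u || Wh_v])
        W = 0.1 * rng.normal(size=(4, 4))
        a = 0.1 * rng.normal(size=8)
        hv = rng.normal(size=4)
        hu = rng.normal(size=(3, 4))
        scores = []
        for u in range(3):
            cat = np.concatenate([W @ hu[u], W @ hv])
            s = float(a @ cat)
            scores.append(s if s > 0 else 0.2 * s)
        expected = oracle_softmax_scores(np.array(scores))
        got = attention_coefficients(hv, hu, W, a)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_weights_in_unit_interval_and_normalized(self, rng):
        w = attention_coefficients(rng.normal(size=4), rng.normal(size=(6, 4)),
                                   rng.normal(size=(4, 4)), rng.normal(size=8))
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w.sum(), 1.0, atol=1e-12)


class TestSegmentSoftmax:
    def test_matches_per_segment_softmax(self, rng):
        scores = Tensor(rng.normal(size=8))
        seg = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        out = segment_softmax(scores, seg, 3).data
        for s in range(3):
            np.testing.assert_allclose(out[seg == s], oracle_softmax_scores(scores.data[seg == s]), atol=1e-12)


class TestMessagePassing:
    def test_single_round_path_graph_matches_oracle(self, kb, rng):
        # 3-node path (propane), channel 2 only; brute-force loop over the
        # score/softmax/message/aggregate/GRU chain
        enc = make_encoder(kb, dim=4, rounds=1, seed=3)
        g = parse_smiles("CCC")
        batch = GraphBatch.from_graphs([bare(g)], enc.label_index)
        got = enc.message_pass(batch).data

        X = g.atom_features()
        h0 = X @ enc.atom_proj.weight.data + enc.atom_proj.bias.data
        ef = g.edge_features() @ enc.bond_proj.weight.data + enc.bond_proj.bias.data
        edges = [(e.i, e.j) for e in g.edges]
        ch = enc.bond_channel
        W = ch.w_att.weight.data
        expected = np.zeros_like(h0)
        sig = lambda v: 1 / (1 + np.exp(-v))
        for v in range(3):
            incoming = [k for k, (i, j) in enumerate(edges) if j == v]
            scores = []
            for k in incoming:
                u = edges[k][0]
                s = (h0[u] @ W) @ ch.a_src.data + (h0[v] @ W) @ ch.a_dst.data
                scores.append(s if s > 0 else 0.2 * s)
            alpha = oracle_softmax_scores(np.array(scores))
            agg = np.zeros(4)
            for w_, k in zip(alpha, incoming):
                u = edges[k][0]
                agg += sig(w_ * (ef[k] @ ch.w_edge.weight.data)) * h0[u]
            expected[v] = oracle_gru(agg, h0[v], enc.gru)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_isolated_atom_finite(self, kb):
        enc = make_encoder(kb, rounds=1)
        batch = GraphBatch.from_graphs([bare(parse_smiles("C"))], enc.label_index)
        h = enc.message_pass(batch).data
        assert np.all(np.isfinite(h))

    def test_automorphic_atoms_equal_states(self, kb):
        enc = make_encoder(kb, rounds=3)
        ag = augment_graph(parse_smiles("CC"), kb)
        batch = GraphBatch.from_graphs([ag], enc.label_index)
        h = enc.message_pass(batch).data
        np.testing.assert_allclose(h[0], h[1], atol=1e-10)

    def test_knowledge_channel_inert_without_virtual_nodes(self, kb):
        enc = make_encoder(kb, rounds=2, seed=5)
        batch = GraphBatch.from_graphs([bare(parse_smiles("CCO"))], enc.label_index)
        before = enc.message_pass(batch).data.copy()
        # perturbing knowledge-channel parameters must not change anything
        enc.know_channel.w_edge.weight.data += 7.0
        enc.know_channel.a_src.data += 3.0
        enc.rel_emb.weight.data += 11.0
        np.testing.assert_array_equal(enc.message_pass(batch).data, before)

    def test_attention_normalization_per_receiver(self, kb, smiles_pool, rng):
        enc = make_encoder(kb, dim=8, seed=2)
        for smi in smiles_pool[::101]:
            ag = augment_graph(parse_smiles(smi, add_hydrogens=True), kb)
            batch = GraphBatch.from_graphs([ag], enc.label_index)
            h = enc.initial_node_states(batch)
            for channel, src, dst in (
                (enc.know_channel, batch.know_src, batch.know_dst),
                (enc.bond_channel, batch.bond_src, batch.bond_dst),
            ):
                if len(src) == 0:
                    continue
                w = channel.attention(h, src, dst, batch.num_nodes).data
                sums = np.zeros(batch.num_nodes)
                np.add.at(sums, dst, w)
                receivers = np.unique(dst)
                np.testing.assert_allclose(sums[receivers], 1.0, atol=1e-6)

    def test_mean_aggregation_supported(self, kb):
        enc = make_encoder(kb, aggregation="mean")
        ag = augment_graph(parse_smiles("CCO"), kb)
        out = enc([ag]).data
        assert np.all(np.isfinite(out))

    def test_bad_aggregation_rejected(self, kb):
        with pytest.raises(ValueError):
            make_encoder(kb, aggregation="median")


def permute_atoms(graph, perm):
    """Relabel atoms of a MolecularGraph by perm[old] = new."""
    from sgatt.molio import AtomNode, BondEdge, MolecularGraph

    nodes = [None] * len(graph.nodes)
    for n in graph.nodes:
        nodes[perm[n.index]] = AtomNode(perm[n.index], n.symbol, n.features)
    edges = [BondEdge(perm[e.i], perm[e.j], e.features) for e in graph.edges]
    return MolecularGraph(nodes=nodes, edges=edges, smiles=graph.smiles,
                          explicit_h=graph.explicit_h, _mol=None)


class TestReadout:
    def test_permutation_invariance(self, kb, rng):
        enc = make_encoder(kb, dim=8, rounds=2, seed=4)
        g = parse_smiles("CCO")
        perm = np.array([2, 0, 1])
        out1 = enc([bare(g)]).data
        out2 = enc([bare(permute_atoms(g, perm))]).data
        np.testing.assert_allclose(out1, out2, atol=1e-8)

    def test_single_node_attention_weight_one(self, kb):
        enc = make_encoder(kb, dim=4, rounds=1, set2set_steps=2)
        batch = GraphBatch.from_graphs([bare(parse_smiles("C"))], enc.label_index)
        states = enc.message_pass(batch)
        attn = segment_softmax((states[batch.atom_rows] * Tensor(np.ones((1, 4)))).sum(axis=-1),
                               batch.atom_graph_ids, 1)
        np.testing.assert_allclose(attn.data, [1.0])
        out = enc.readout(states, batch).data
        assert out.shape == (1, 4) and np.all(np.isfinite(out))

    def test_set2set_matches_manual_recurrence(self, kb):
        # oracle: unroll the T=2 Set2Set recurrence by hand
        enc = make_encoder(kb, dim=4, rounds=1, set2set_steps=2, seed=9)
        g = parse_smiles("CCO")
        batch = GraphBatch.from_graphs([bare(g)], enc.label_index)
        states = enc.message_pass(batch)
        got = enc.readout(states, batch).data[0]

        hN = states.data[batch.atom_rows]
        q_star = np.zeros(8)
        hl, cl = np.zeros(4), np.zeros(4)
        for _ in range(2):
            hl, cl = oracle_lstm(q_star, hl, cl, enc.s2s_lstm)
            e = hN @ hl
            a = oracle_softmax_scores(e)
            r = a @ hN
            q_star = np.concatenate([hl, r])
        expected = q_star @ enc.out_proj.weight.data + enc.out_proj.bias.data
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_batched_equals_individual(self, kb):
        enc = make_encoder(kb, dim=8, rounds=2, seed=6)
        graphs = [augment_graph(parse_smiles(s), kb) for s in ("CCO", "c1ccccc1", "CC(=O)O")]
        together = enc(graphs).data
        solo = np.concatenate([enc([g]).data for g in graphs])
        np.testing.assert_allclose(together, solo, atol=1e-8)
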