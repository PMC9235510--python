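"""Graph encoder: message passing, attention and the pooled embedding."""

import numpy as np
import pytest
from rdkit import Chem

from molpotency.chem import MolGraph, Molecule, mol_to_graph, parse_smiles
from molpotency.encoder import (
    AttentionOutput,
    EncoderParams,
    NodeStates,
    TableEmbeddingProvider,
    attend,
    encode_graph,
    init_states,
    message_step,
)


def graph_of(rdmol):
    """Graph of an RDKit mol preserving its current atom numbering."""
    return mol_to_graph(Molecule(id="", smiles="", canonical_smiles="", _mol=rdmol))


def small_params(**kw):
    defaults = dict(L=2, hidden_dim=8, d=8, n_heads=2, seed=0)
    defaults.update(kw)
    return EncoderParams(**defaults)


class TestInitStates:
    def test_seeded_determinism(self, ethanol):
        g = mol_to_graph(ethanol)
        s1 = init_states(g, small_params(seed=5))
        s2 = init_states(g, small_params(seed=5))
        np.testing.assert_array_equal(s1.h, s2.h)

    def test_zero_features_zero_bias_give_zero_states(self):
        p = small_params()
        g = MolGraph(
            nodes=np.zeros((4, p.n_atom_features)),
            edges=np.empty((0, 2), dtype=np.int64),
            edge_features=np.empty((0, p.n_bond_features)),
            n_nodes=4,
        )
        assert (init_states(g, p).h == 0).all()

    def test_one_state_per_node(self, benzene):
        s = init_states(mol_to_graph(benzene), small_params())
        assert s.h.shape == (6, 8)


class TestMessageStep:
    def test_edgeless_graph_closed_form(self):
        # no neighbors -> m = 0 -> h = sigma(b) for every node
        p = small_params(activation="relu")
        p.weights["b_0"] = np.linspace(-1, 1, p.hidden_dim)
        g = MolGraph(
            nodes=np.random.default_rng(0).normal(size=(3, p.n_atom_features)),
            edges=np.empty((0, 2), dtype=np.int64),
            edge_features=np.empty((0, p.n_bond_features)),
            n_nodes=3,
        )
        s = message_step(g, init_states(g, p), 0, p)
        expected = np.maximum(p.weights["b_0"], 0)
        np.testing.assert_allclose(s.h, np.tile(expected, (3, 1)))

    def test_identity_maps_sum_neighbor_states(self):
        # identity sigma/W, zero bias and edge map: h_i = sum of neighbor h_j
        p = small_params(activation="identity", L=1)
        h = p.hidden_dim
        p.weights["W_msg_0"] = np.eye(h)
        p.weights["W_edge_0"] = np.zeros((p.n_bond_features, h))
        p.weights["W_0"] = np.eye(h)
        p.weights["b_0"] = np.zeros(h)
        # 3-node path graph 0-1-2
        g = MolGraph(
            nodes=np.zeros((3, p.n_atom_features)),
            edges=np.array([[0, 1], [1, 0], [1, 2], [2, 1]]),
            edge_features=np.zeros((4, p.n_bond_features)),
            n_nodes=3,
        )
        h0 = np.arange(3 * h, dtype=float).reshape(3, h)
        s = message_step(g, NodeStates(h=h0), 0, p)
        np.testing.assert_allclose(s.h[0], h0[1])
        np.testing.assert_allclose(s.h[1], h0[0] + h0[2])
        np.testing.assert_allclose(s.h[2], h0[1])

    def test_node_relabeling_permutes_states(self, random_molecules):
        p = small_params()
        m = random_molecules[0]
        perm = [int(x) for x in np.random.default_rng(3).permutation(m.n_heavy_atoms)]
        g1 = mol_to_graph(m)
        g2 = graph_of(Chem.RenumberAtoms(m.rdkit_mol, perm))
        s1 = message_step(g1, init_states(g1, p), 0, p)
        s2 = message_step(g2, init_states(g2, p), 0, p)
        # perm[i] = old index of new atom i under RenumberAtoms
        np.testing.assert_allclose(s2.h, s1.h[perm], atol=1e-10)


class TestAttention:
    def test_weights_normalize_per_node(self, random_molecules):
        p = small_params()
        for m in random_molecules[:10]:
            g = mol_to_graph(m)
            out = attend(init_states(g, p), p)
            np.testing.assert_allclose(out.attn_weights.sum(axis=2), 1.0, atol=1e-12)
            assert (out.attn_weights >= 0).all()

    def test_identical_keys_give_mean_of_values(self):
        p = small_params(n_heads=1)
        p.weights["W_k"] = np.zeros((p.hidden_dim, p.d))  # all keys identical
        h = np.random.default_rng(1).normal(size=(5, p.hidden_dim))
        out = attend(NodeStates(h=h), p)
        v = h @ p.weights["W_v"]
        for i in range(5):
            np.testing.assert_allclose(out.A[i], v.mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("scale_mode,scale", [("sqrt_d", np.sqrt(2)), ("d", 2.0)])
    def test_three_node_hand_computation(self, scale_mode, scale):
        p = EncoderParams(L=1, hidden_dim=2, d=2, n_heads=1, seed=0, attn_scale=scale_mode)
        p.weights["W_q"] = np.eye(2)
        p.weights["W_k"] = np.eye(2)
        p.weights["W_v"] = np.eye(2)
        h = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = attend(NodeStates(h=h), p)
        logits = h @ h.T / scale
        for i in range(3):
            w = np.exp(logits[i] - logits[i].max())
            w /= w.sum()
            np.testing.assert_allclose(out.A[i], w @ h, atol=1e-12)


class TestEncodeGraph:
    def test_permutation_invariance_over_50_graphs(self, random_molecules):
        p = small_params(L=3, hidden_dim=16, d=16)
        rng = np.random.default_rng(7)
        for m in random_molecules[:50]:
            e1 = encode_graph(mol_to_graph(m), p)
            perm = [int(x) for x in rng.permutation(m.n_heavy_atoms)]
            e2 = encode_graph(graph_of(Chem.RenumberAtoms(m.rdkit_mol, perm)), p)
            assert np.abs(e1 - e2).max() < 1e-5

    def test_single_node_graph_equals_attended_vector(self):
        p = small_params()
        g = mol_to_graph(parse_smiles("C"))
        s = init_states(g, p)
        for layer in range(p.L):
            s = message_step(g, s, layer, p)
        np.testing.assert_allclose(encode_graph(g, p), attend(s, p).A[0])

    def test_two_disconnected_copies_pool_to_single_copy(self, ethanol):
        p = small_params()
        g = mol_to_graph(ethanol)
        n = g.n_nodes
        double = MolGraph(
            nodes=np.vstack([g.nodes, g.nodes]),
            edges=np.vstack([g.edges, g.edges + n]),
            edge_features=np.vstack([g.edge_features, g.edge_features]),
            n_nodes=2 * n,
        )
        # attention mixes the two copies, but by symmetry both copies carry
        # identical states, so the pooled embedding matches the single copy
        np.testing.assert_allclose(encode_graph(double, p), encode_graph(g, p), atol=1e-8)

    def test_l0_identity_projections_reduce_to_mean_pooled_atom_features(self):
        nf = 6
        p = EncoderParams(L=0, hidden_dim=nf, d=nf, n_heads=1, seed=0)
        p.weights["W_in"] = np.eye(nf)
        p.weights["b_in"] = np.zeros(nf)
        p.weights["W_q"] = np.zeros((nf, nf))
        p.weights["W_k"] = np.zeros((nf, nf))
        p.weights["W_v"] = np.eye(nf)
        g = mol_to_graph(parse_smiles("CC(=O)O"))
        np.testing.assert_allclose(encode_graph(g, p), g.nodes.mean(axis=0), atol=1e-12)


class TestExternalEmbeddings:
    def test_table_lookup_verbatim(self):
        provider = TableEmbeddingProvider({"m1": [0.0, 0.0], "m2": [1.0, 2.0]})
        assert provider.dim == 2
        np.testing.assert_array_equal(provider("m1"), [0.0, 0.0])

    def test_missing_id_errors_with_name(self):
        provider = TableEmbeddingProvider({"m1": [0.0, 0.0]})
        with pytest.raises(KeyError, match="m2"):
            provider("m2")

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError):
            TableEmbeddingProvider({"a": [1.0], "b": [1.0, 2.0]})

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        from molpotency.encoder import load_external_embeddings

        pd.DataFrame({"id": ["m1", "m2"], "e0": [0.5, 1.5], "e1": [2.5, 3.5]}).to_csv(
            tmp_path / "emb.csv", index=False
        )
        provider = load_external_embeddings(tmp_path / "emb.csv")
        np.testing.assert_allclose(provider("m2"), [1.5, 3.5])
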