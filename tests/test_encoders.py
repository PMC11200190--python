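"""Encoder contracts: embedding lookup, CNN blocks, D-MPNN message passing."""

import numpy as np
import pytest

from dtifuse.featurize import MolecularGraph, TokenVector, smiles_to_graph
from dtifuse.encoders import (CnnBlockParams, ConfigError, DmpnnParams,
                              EmbeddingTable, ModalFeatureMatrix, cnn_block,
                              dmpnn_encode, dmpnn_init_edges, dmpnn_iterate,
                              dmpnn_node_features, embed_tokens)

from reference_impls import ref_dmpnn


def toy_path_graph():
    """Hand-built 3-atom path 0-1-2 with scalar features x=[1,2,3], e=1."""
    return MolecularGraph(
        n_atoms=3,
        atom_features=np.array([[1.0], [2.0], [3.0]]),
        edge_src=np.array([0, 1, 1, 2]),
        edge_dst=np.array([1, 0, 2, 1]),
        bond_features=np.ones((4, 1)),
        rev_edge=np.array([1, 0, 3, 2]),
    )


def identity_params(message_fn="edge_hidden_sum", T=1):
    """Scalar weights: every linear map sums its (two) inputs."""
    ones2 = np.ones((2, 1))
    return DmpnnParams(W_b=ones2, W_x=np.ones((1, 1)), W_f=ones2,
                       b_f=np.zeros(1), W_alpha=ones2, b_alpha=np.zeros(1),
                       T=T, message_fn=message_fn)


def random_params(rng, f_atom, f_bond, d, T=2, message_fn="mean"):
    return DmpnnParams(
        W_b=rng.normal(size=(f_atom + f_bond, d)),
        W_x=rng.normal(size=(f_atom, d)),
        W_f=rng.normal(size=(2 * d, d)), b_f=rng.normal(size=d),
        W_alpha=rng.normal(size=(f_atom + d, d)), b_alpha=rng.normal(size=d),
        T=T, message_fn=message_fn)


class TestEmbedding:
    def test_lookup_semantics(self):
        table = EmbeddingTable(np.vstack([np.zeros(3), np.eye(3)]))
        tv = TokenVector(np.array([2, 1, 0]), np.array([True, True, False]), 2)
        out = embed_tokens(tv, table)
        assert np.allclose(out.values[0], [0, 1, 0])
        assert np.allclose(out.values[1], [1, 0, 0])
        assert np.allclose(out.values[2], 0.0)

    def test_padding_rows_zero_and_duplicates_identical(self, rng):
        w = rng.normal(size=(10, 4))
        w[0] = 0
        table = EmbeddingTable(w)
        tv = TokenVector(np.array([5, 5, 0]), np.array([True, True, False]), 2)
        out = embed_tokens(tv, table)
        assert np.allclose(out.values[0], out.values[1])
        assert np.allclose(out.values[2], 0.0)

    def test_out_of_vocab_id(self):
        table = EmbeddingTable(np.zeros((4, 2)))
        tv = TokenVector(np.array([4]), np.array([True]), 1)
        with pytest.raises(IndexError):
            embed_tokens(tv, table)


class TestCnnBlock:
    def test_identity_convolution(self, rng):
        x = np.abs(rng.normal(size=(6, 4)))      # nonneg so ReLU is identity
        X = ModalFeatureMatrix(x, np.ones(6, dtype=bool))
        params = CnnBlockParams(kernels=[np.eye(4)[None, :, :]],
                                biases=[np.zeros(4)])
        out = cnn_block(X, params)
        assert np.allclose(out.values, x)

    def test_zero_input_zero_output(self):
        X = ModalFeatureMatrix(np.zeros((5, 3)), np.ones(5, dtype=bool))
        params = CnnBlockParams(
            kernels=[np.random.default_rng(0).normal(size=(3, 3, 3))],
            biases=[np.zeros(3)])
        assert np.allclose(cnn_block(X, params).values, 0.0)

    def test_same_padding_shape_and_mask_hygiene(self, rng):
        mask = np.array([True] * 5 + [False] * 2)
        x = rng.normal(size=(7, 8))
        x[~mask] = 0
        X = ModalFeatureMatrix(x, mask)
        params = CnnBlockParams(
            kernels=[rng.normal(size=(3, 8, 8)), rng.normal(size=(5, 8, 8)),
                     rng.normal(size=(7, 8, 6))],
            biases=[rng.normal(size=8), rng.normal(size=8), rng.normal(size=6)])
        out = cnn_block(X, params)
        assert out.values.shape == (7, 6)
        assert np.allclose(out.values[~mask], 0.0)   # masked rows re-zeroed

    def test_channel_mismatch(self, rng):
        X = ModalFeatureMatrix(rng.normal(size=(4, 5)), np.ones(4, dtype=bool))
        params = CnnBlockParams(kernels=[rng.normal(size=(3, 8, 8))],
                                biases=[np.zeros(8)])
        with pytest.raises(ValueError, match="channel"):
            cnn_block(X, params)


class TestDmpnn:
    def test_edge_init_zero_weights_and_empty_graph(self, rng):
        g = smiles_to_graph("CCO")
        p = random_params(rng, g.atom_features.shape[1],
                          g.bond_features.shape[1], 4)
        p.W_b = np.zeros_like(p.W_b)
        assert np.allclose(dmpnn_init_edges(g, p), 0.0)
        single = smiles_to_graph("C")
        assert dmpnn_init_edges(single, random_params(
            rng, single.atom_features.shape[1], 12, 4)).shape[0] == 0

    def test_edge_init_hand_case(self):
        # 2-atom toy, scalar features: h0 = ReLU(x_src + e)
        g = MolecularGraph(2, np.array([[2.0], [-3.0]]),
                           np.array([0, 1]), np.array([1, 0]),
                           np.array([[1.0], [1.0]]), np.array([1, 0]))
        h0 = dmpnn_init_edges(g, identity_params())
        assert np.allclose(h0, [[3.0], [0.0]])   # relu(2+1), relu(-3+1)

    def test_two_atom_messages_are_zero(self, rng):
        # N(v)\{w} is empty on a 2-atom molecule at every step, so the
        # update reduces to h_{t+1} = relu(W_f [h_t ; 0])
        g = smiles_to_graph("CO")
        p = random_params(rng, g.atom_features.shape[1],
                          g.bond_features.shape[1], 6, T=3)
        h0 = dmpnn_init_edges(g, p)
        h = h0
        for _ in range(3):
            h = np.maximum(
                np.concatenate([h, np.zeros_like(h)], axis=1) @ p.W_f + p.b_f,
                0.0)
        assert np.allclose(dmpnn_iterate(g, h0, p), h, atol=1e-10)

    def test_three_atom_path_hand_values(self):
        # frozen from the scalar derivation: x=[1,2,3], e=1, sum-weights
        g = toy_path_graph()
        out = dmpnn_encode(g, identity_params("edge_hidden_sum", T=1))
        assert np.allclose(out.values.ravel(), [8.0, 8.0, 8.0])
        out_mean = dmpnn_encode(g, identity_params("mean", T=1))
        assert np.allclose(out_mean.values.ravel(), [7.0, 8.0, 23.0 / 3.0])

    def test_path_message_uses_only_upstream_edge(self):
        # for edge B->C on path A-B-C the t=1 message aggregates A->B only
        g = toy_path_graph()
        p = identity_params("edge_hidden_sum", T=1)
        h0 = dmpnn_init_edges(g, p)           # rows: (0,1),(1,0),(1,2),(2,1)
        h1 = dmpnn_iterate(g, h0, p)
        assert np.isclose(h1[2, 0], max(h0[2, 0] + h0[0, 0], 0.0))

    @pytest.mark.parametrize("message_fn", ["mean", "edge_hidden_sum"])
    def test_matches_nested_loop_oracle(self, rng, molecule_pool, message_fn):
        small = [s for s in molecule_pool
                 if smiles_to_graph(s).n_atoms <= 8][:20]
        assert len(small) >= 5
        for smi in small:
            g = smiles_to_graph(smi)
            p = random_params(rng, g.atom_features.shape[1],
                              g.bond_features.shape[1], 5, T=2,
                              message_fn=message_fn)
            ours = dmpnn_encode(g, p).values
            ref = ref_dmpnn(g.atom_features, g.directed_edges,
                            g.bond_features, p.W_b, p.W_x, p.W_f, p.b_f,
                            p.W_alpha, p.b_alpha, p.T, message_fn)
            assert np.allclose(ours, ref, atol=1e-6)

    def test_node_features_no_pooling(self, rng, molecule_pool):
        for smi in molecule_pool[:20]:
            g = smiles_to_graph(smi)
            p = random_params(rng, g.atom_features.shape[1],
                              g.bond_features.shape[1], 4)
            out = dmpnn_encode(g, p)
            assert out.values.shape == (g.n_atoms, 4)
            assert out.mask.all()

    def test_isolated_atom_node_feature(self, rng):
        g = smiles_to_graph("C")
        p = random_params(rng, g.atom_features.shape[1], 12, 4)
        out = dmpnn_encode(g, p)
        expected = np.maximum(
            np.concatenate([g.atom_features[0], np.zeros(4)]) @ p.W_alpha
            + p.b_alpha, 0.0)
        assert np.allclose(out.values[0], expected)

    def test_permutation_equivariance(self, rng, molecule_pool):
        for smi in molecule_pool[:25]:
            g = smiles_to_graph(smi)
            if g.n_atoms < 2:
                continue
            p = random_params(rng, g.atom_features.shape[1],
                              g.bond_features.shape[1], 4)
            perm = rng.permutation(g.n_atoms)
            inv = np.argsort(perm)
            gp = MolecularGraph(
                n_atoms=g.n_atoms,
                atom_features=g.atom_features[perm],
                edge_src=inv[g.edge_src], edge_dst=inv[g.edge_dst],
                bond_features=g.bond_features, rev_edge=g.rev_edge)
            out = dmpnn_encode(g, p).values
            out_p = dmpnn_encode(gp, p).values
            assert np.allclose(out_p, out[perm], atol=1e-6)

    def test_depth_sweep_outputs_finite(self, rng, molecule_pool):
        g = smiles_to_graph(molecule_pool[0])
        for T in range(1, 6):
            p = random_params(rng, g.atom_features.shape[1],
                              g.bond_features.shape[1], 4, T=T)
            assert np.isfinite(dmpnn_encode(g, p).values).all()

    def test_invalid_depth_rejected(self, rng):
        g = smiles_to_graph("CCO")
        p = random_params(rng, g.atom_features.shape[1],
                          g.bond_features.shape[1], 4)
        p.T = 0
        with pytest.raises(ConfigError):
            dmpnn_iterate(g, dmpnn_init_edges(g, p), p)
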