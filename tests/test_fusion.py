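"""Fusion contracts: masked attention, cross-attention, hierarchical fusion."""

import numpy as np
import pytest

from dtifuse.encoders import ModalFeatureMatrix
from dtifuse.fusion import (FusionInputError, cross_attention, hmsa_fuse,
                            hmsa_level, masked_self_attention)

from conftest import random_attention_params, random_modal
from reference_impls import ref_attention


class TestMaskedSelfAttention:
    def test_singleton_token(self, rng):
        X = random_modal(rng, 1, 4)
        p = random_attention_params(rng, 4)
        out = masked_self_attention(X, p)
        assert np.allclose(out.A, [[1.0]])
        assert np.allclose(out.H[0], X.values[0] @ p.W_V + p.b_V)

    def test_identical_keys_give_uniform_rows(self, rng):
        v = rng.normal(size=4)
        X = ModalFeatureMatrix(np.vstack([v, v]), np.ones(2, dtype=bool))
        p = random_attention_params(rng, 4)
        out = masked_self_attention(X, p)
        assert np.allclose(out.A, 0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 9))
            d = int(rng.integers(2, 7))
            masked_tail = int(rng.integers(0, L))
            X = random_modal(rng, L, d, masked_tail)
            p = random_attention_params(rng, d)
            out = masked_self_attention(X, p)
            H, A = ref_attention(X.values, X.values, p.W_Q, p.W_K, p.W_V,
                                 p.b_Q, p.b_K, p.b_V, X.mask, X.mask)
            assert np.allclose(out.H, H, atol=1e-6)
            assert np.allclose(out.A, A, atol=1e-6)

    def test_row_stochastic_with_exact_zero_masked_keys(self, rng):
        X = random_modal(rng, 6, 5, masked_tail=2)
        p = random_attention_params(rng, 5)
        out = masked_self_attention(X, p)
        assert np.all(out.A[:, ~X.mask] == 0.0)
        assert np.allclose(out.A[X.mask].sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(out.H[~X.mask], 0.0)

    def test_all_masked_rejected(self, rng):
        X = ModalFeatureMatrix(np.zeros((3, 4)), np.zeros(3, dtype=bool))
        with pytest.raises(FusionInputError):
            masked_self_attention(X, random_attention_params(rng, 4))

    def test_multi_head_shapes(self, rng):
        X = random_modal(rng, 5, 8)
        p = random_attention_params(rng, 8, n_heads=2)
        out = masked_self_attention(X, p)
        assert out.H.shape == (5, 8)
        assert out.A.shape == (2, 5, 5)
        assert np.allclose(out.A.sum(axis=-1), 1.0, atol=1e-6)


class TestCrossAttention:
    def test_single_key_forces_full_weight(self, rng):
        Xq = random_modal(rng, 2, 3)
        Xkv = random_modal(rng, 1, 3)
        p = random_attention_params(rng, 3)
        out = cross_attention(Xq, Xkv, p)
        v = Xkv.values[0] @ p.W_V + p.b_V
        assert np.allclose(out.H[0], v) and np.allclose(out.H[1], v)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            Lq, Lk = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            d = int(rng.integers(2, 6))
            Xq = random_modal(rng, Lq, d)
            Xkv = random_modal(rng, Lk, d, int(rng.integers(0, Lk)))
            p = random_attention_params(rng, d)
            out = cross_attention(Xq, Xkv, p)
            H, A = ref_attention(Xq.values, Xkv.values, p.W_Q, p.W_K, p.W_V,
                                 p.b_Q, p.b_K, p.b_V, Xq.mask, Xkv.mask)
            assert np.allclose(out.H, H, atol=1e-6)
            assert np.allclose(out.A, A, atol=1e-6)

    def test_output_confined_to_value_row_span(self, rng):
        # the motivating limitation: H rows are weighted combinations of
        # V rows, so they live in span(V) even though queries vary freely
        Xq = random_modal(rng, 4, 6)
        Xkv = random_modal(rng, 3, 6)
        p = random_attention_params(rng, 6)
        out = cross_attention(Xq, Xkv, p)
        V = Xkv.values @ p.W_V + p.b_V
        _, res, _, _ = np.linalg.lstsq(V.T, out.H.T, rcond=None)
        if res.size:
            assert res.max() < 1e-8
        else:
            proj = V.T @ np.linalg.pinv(V.T) @ out.H.T
            assert np.abs(proj - out.H.T).max() < 1e-8

    def test_empty_key_stream_rejected(self, rng):
        Xq = random_modal(rng, 2, 3)
        bad = ModalFeatureMatrix(np.zeros((0, 3)), np.zeros(0, dtype=bool))
        with pytest.raises(FusionInputError):
            cross_attention(Xq, bad, random_attention_params(rng, 3))


class TestHmsaLevel:
    def test_degenerate_empty_second_stream(self, rng):
        Xa = random_modal(rng, 4, 5)
        Xb = ModalFeatureMatrix(np.zeros((0, 5)), np.zeros(0, dtype=bool))
        p = random_attention_params(rng, 5)
        Ha, Hb = hmsa_level(Xa, Xb, p)
        solo = masked_self_attention(Xa, p)
        assert np.allclose(Ha, solo.H) and Hb.shape == (0, 5)

    def test_equals_block_assembly(self, rng):
        # Assemble the four Q K^T blocks by hand, apply the joint softmax
        # and multiply the stacked values: must reproduce (Ha, Hb).
        for _ in range(25):
            La, Lb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            d = int(rng.integers(2, 6))
            Xa, Xb = random_modal(rng, La, d), random_modal(rng, Lb, d)
            p = random_attention_params(rng, d)
            Ha, Hb = hmsa_level(Xa, Xb, p)
            Qa, Ka, Va = (Xa.values @ p.W_Q + p.b_Q,
                          Xa.values @ p.W_K + p.b_K,
                          Xa.values @ p.W_V + p.b_V)
            Qb, Kb, Vb = (Xb.values @ p.W_Q + p.b_Q,
                          Xb.values @ p.W_K + p.b_K,
                          Xb.values @ p.W_V + p.b_V)
            logits = np.block([[Qa @ Ka.T, Qa @ Kb.T],
                               [Qb @ Ka.T, Qb @ Kb.T]]) / np.sqrt(d)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            A = e / e.sum(axis=1, keepdims=True)
            H = A @ np.vstack([Va, Vb])
            assert np.allclose(Ha, H[:La], atol=1e-6)
            assert np.allclose(Hb, H[La:], atol=1e-6)

    def test_inter_modal_attention_mass_positive(self, rng):
        Xa, Xb = random_modal(rng, 4, 5), random_modal(rng, 3, 5)
        p = random_attention_params(rng, 5)
        _, _, out = hmsa_level(Xa, Xb, p, return_attention=True)
        off_block = out.A[:4, 4:]
        assert np.all(off_block > 0.0)

    def test_output_escapes_single_value_span(self, rng):
        # unlike cross-attention, the joint-stream output mixes both
        # value sets, so Ha generically leaves span(Vb)
        Xa, Xb = random_modal(rng, 4, 6), random_modal(rng, 3, 6)
        p = random_attention_params(rng, 6)
        Ha, _ = hmsa_level(Xa, Xb, p)
        Vb = Xb.values @ p.W_V + p.b_V
        proj = Ha @ np.linalg.pinv(Vb) @ Vb
        # pinv solves row-space least squares: residual must be material
        assert np.abs(Ha - proj).max() > 1e-6

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            hmsa_level(random_modal(rng, 3, 4), random_modal(rng, 3, 5),
                       random_attention_params(rng, 4))


class TestHmsaFuse:
    def _modalities(self, rng, d=5):
        return (random_modal(rng, 6, d, 1, "smiles"),
                random_modal(rng, 4, d, 0, "graph"),
                random_modal(rng, 8, d, 2, "seq"),
                random_modal(rng, 7, d, 1, "mer"))

    def _params(self, rng, d=5):
        return (random_attention_params(rng, d),
                random_attention_params(rng, d),
                random_attention_params(rng, d))

    def test_shapes(self, rng):
        Xs, Xg, Xq, Xm = self._modalities(rng)
        pooled, bundle = hmsa_fuse(Xs, Xg, Xq, Xm, *self._params(rng))
        assert bundle.D_smiles.shape == Xs.values.shape
        assert bundle.D_graph.shape == Xg.values.shape
        assert bundle.D_seq.shape == Xq.values.shape
        assert bundle.D_mer.shape == Xm.values.shape
        for z in (pooled.Z_smiles, pooled.Z_graph, pooled.Z_seq, pooled.Z_mer):
            assert z.shape == (5,) and np.isfinite(z).all()

    def test_zero_value_projection_isolates_residual(self, rng):
        Xs, Xg, Xq, Xm = self._modalities(rng)
        params = self._params(rng)
        for p in params:
            p.W_V = np.zeros_like(p.W_V)
            p.b_V = np.zeros_like(p.b_V)
        pooled, _ = hmsa_fuse(Xs, Xg, Xq, Xm, *params)
        for z, X in zip((pooled.Z_smiles, pooled.Z_graph, pooled.Z_seq,
                         pooled.Z_mer), (Xs, Xg, Xq, Xm)):
            expected = X.values[X.mask].max(axis=0)
            assert np.allclose(z, expected)

    def test_graph_row_permutation_invariance_of_pools(self, rng):
        Xs, Xg, Xq, Xm = self._modalities(rng)
        params = self._params(rng)
        pooled, _ = hmsa_fuse(Xs, Xg, Xq, Xm, *params)
        perm = rng.permutation(Xg.values.shape[0])
        Xg2 = ModalFeatureMatrix(Xg.values[perm], Xg.mask[perm], "graph")
        pooled2, _ = hmsa_fuse(Xs, Xg2, Xq, Xm, *params)
        for a, b in [(pooled.Z_smiles, pooled2.Z_smiles),
                     (pooled.Z_graph, pooled2.Z_graph),
                     (pooled.Z_seq, pooled2.Z_seq),
                     (pooled.Z_mer, pooled2.Z_mer)]:
            assert np.allclose(a, b, atol=1e-6)

    def test_empty_modality_rejected(self, rng):
        Xs, Xg, Xq, Xm = self._modalities(rng)
        bad = ModalFeatureMatrix(np.zeros((0, 5)), np.zeros(0, dtype=bool))
        with pytest.raises(FusionInputError):
            hmsa_fuse(bad, Xg, Xq, Xm, *self._params(rng))

    def test_attention_matrix_export(self, rng, tmp_path):
        import pandas as pd
        from dtifuse.fusion import export_attention
        X = random_modal(rng, 4, 3)
        out = masked_self_attention(X, random_attention_params(rng, 3))
        path = tmp_path / "attention.tsv"
        export_attention(out.A, str(path))
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["query", "key", "weight"]
        assert len(df) == 16
        back = df.pivot(index="query", columns="key", values="weight").to_numpy()
        assert np.allclose(back, out.A, atol=1e-9)

    def test_deterministic(self, rng):
        Xs, Xg, Xq, Xm = self._modalities(rng)
        params = self._params(rng)
        p1, _ = hmsa_fuse(Xs, Xg, Xq, Xm, *params)
        p2, _ = hmsa_fuse(Xs, Xg, Xq, Xm, *params)
        assert np.array_equal(p1.Z_smiles, p2.Z_smiles)
        assert np.array_equal(p1.Z_mer, p2.Z_mer)
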