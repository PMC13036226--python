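"""Attention primitives against independent naive oracles."""

import numpy as np
import pytest

from conftest import naive_multihead_attention
from mmfluorfuse import autodiff as ad
from mmfluorfuse.attention import (TokenSequence, compute_gate,
                                   cross_attention, global_self_attention,
                                   init_attention, init_gate, init_qkv,
                                   partition_qkv, window_self_attention)
from mmfluorfuse.errors import DimensionError


def _identity_params(c, heads=1):
    p = init_attention(c, heads, np.random.default_rng(0))
    for name in ("wq", "wk", "wv", "wo"):
        getattr(p, name).data = np.eye(c)
    for name in ("bq", "bk", "bv", "bo"):
        getattr(p, name).data = np.zeros(c)
    return p


class TestPartition:
    def test_slice_sizes_and_reassembly(self):
        rng = np.random.default_rng(0)
        tokens = rng.normal(size=(10, 8))
        seq = TokenSequence(tokens, (4, 4, 2), grid_side=2)
        p = init_qkv(8, 2, rng)
        (qi, ki, vi), (qt, kt, vt), (qg, kg, vg) = partition_qkv(seq, p)
        assert qi.shape == (4, 8) and qt.shape == (4, 8) and qg.shape == (2, 8)
        full_q = tokens @ p.wq.data + p.bq.data
        reassembled = np.concatenate([qi.data, qt.data, qg.data])
        assert np.allclose(reassembled, full_q, atol=1e-12)

    def test_identity_projection_returns_raw_slices(self):
        tokens = np.random.default_rng(1).normal(size=(10, 6))
        seq = TokenSequence(tokens, (4, 4, 2), grid_side=2)
        p = _identity_params(6)
        (qi, _, _), (qt, _, _), (qg, _, _) = partition_qkv(seq, p)
        assert np.allclose(qi.data, tokens[:4])
        assert np.allclose(qt.data, tokens[4:8])
        assert np.allclose(qg.data, tokens[8:])

    def test_bad_boundaries(self):
        with pytest.raises(DimensionError):
            TokenSequence(np.zeros((10, 4)), (4, 4, 4), grid_side=2)
        with pytest.raises(DimensionError):
            TokenSequence(np.zeros((10, 4)), (5, 3, 2), grid_side=2)


class TestGlobalAttention:
    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 16))
        p = init_attention(16, 4, rng, init_scale=0.5)
        ours = global_self_attention(x, p).data
        assert np.allclose(ours, naive_multihead_attention(x, x, p), atol=1e-6)

    def test_single_token_identity_projections(self):
        x = np.random.default_rng(3).normal(size=(1, 6))
        assert np.allclose(global_self_attention(x, _identity_params(6)).data, x)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 8))
        p = init_attention(8, 2, rng, init_scale=0.4)
        perm = rng.permutation(9)
        out = global_self_attention(x, p).data
        out_perm = global_self_attention(x[perm], p).data
        assert np.allclose(out[perm], out_perm, atol=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(7, 8))
        _, w = global_self_attention(x, init_attention(8, 2, rng), return_weights=True)
        assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-5)


class TestCrossAttention:
    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(5, 16)), rng.normal(size=(9, 16))
        p = init_attention(16, 4, rng, init_scale=0.5)
        assert np.allclose(cross_attention(a, b, p).data,
                           naive_multihead_attention(a, b, p), atol=1e-6)

    def test_single_kv_row_broadcast(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(6, 4)), rng.normal(size=(1, 4))
        out = cross_attention(a, b, _identity_params(4)).data
        assert np.allclose(out, np.repeat(b, 6, axis=0))

    def test_outputs_convex_combinations_of_projected_values(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(7, 2))
        p = init_attention(2, 1, rng, init_scale=0.8)
        out, w = cross_attention(a, b, p, return_weights=True)
        w = w.data[0, 0]  # single head
        assert (w >= 0).all() and np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        v = b @ p.wv.data + p.bv.data
        recon = (w @ v) @ p.wo.data + p.bo.data
        assert np.allclose(recon, out.data, atol=1e-10)

    def test_width_mismatch(self):
        with pytest.raises(DimensionError):
            cross_attention(np.zeros((3, 4)), np.zeros((3, 6)), _identity_params(4))


class TestWindowAttention:
    def test_full_window_equals_global(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(64, 16))  # 8x8 grid
        p = init_attention(16, 4, rng, init_scale=0.5)
        windowed = window_self_attention(x, grid_side=8, window=8, p=p).data
        assert np.allclose(windowed, global_self_attention(x, p).data, atol=1e-6)

    def test_window_one_identity_value_path(self):
        x = np.random.default_rng(10).normal(size=(16, 4))
        out = window_self_attention(x, grid_side=4, window=1,
                                    p=_identity_params(4)).data
        assert np.allclose(out, x)

    def test_tile_locality_matches_per_tile_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(16, 8))  # 4x4 grid, 2x2 windows
        p = init_attention(8, 2, rng, init_scale=0.5)
        out = window_self_attention(x, grid_side=4, window=2, p=p).data
        grid = x.reshape(4, 4, 8)
        for wi in range(2):
            for wj in range(2):
                tile = grid[2 * wi:2 * wi + 2, 2 * wj:2 * wj + 2].reshape(4, 8)
                ref = naive_multihead_attention(tile, tile, p)
                got = out.reshape(4, 4, 8)[2 * wi:2 * wi + 2,
                                           2 * wj:2 * wj + 2].reshape(4, 8)
                assert np.allclose(got, ref, atol=1e-6)

    def test_non_divisible_grid(self):
        with pytest.raises(DimensionError):
            window_self_attention(np.zeros((16, 4)), grid_side=4, window=3,
                                  p=_identity_params(4))


class TestGate:
    def test_zero_weights_give_half(self):
        g = init_gate(4, np.random.default_rng(0))
        for t in g.tensors().values():
            t.data = np.zeros_like(t.data)
        out = compute_gate(np.ones((3, 4)), np.ones((2, 4)), g)
        assert np.allclose(out.data, 0.5)

    def test_bounded_open_interval(self):
        rng = np.random.default_rng(1)
        g = init_gate(6, rng, init_scale=0.5)
        for _ in range(200):
            img = rng.normal(size=(5, 6))
            txt = rng.normal(size=(3, 6))
            val = compute_gate(img, txt, g).data
            assert 0.0 < val < 1.0

    def test_invariant_to_image_token_permutation(self):
        rng = np.random.default_rng(2)
        g = init_gate(4, rng, init_scale=0.5)
        img = rng.normal(size=(6, 4))
        txt = rng.normal(size=(2, 4))
        a = compute_gate(img, txt, g).data
        b = compute_gate(img[rng.permutation(6)], txt, g).data
        assert np.allclose(a, b)

    def test_empty_modality_rejected(self):
        g = init_gate(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            compute_gate(np.zeros((0, 4)), np.zeros((2, 4)), g)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        g = init_gate(3, rng, init_scale=0.5)
        img = rng.normal(size=(4, 3))
        txt = rng.normal(size=(2, 3))

        def loss_value():
            return float(compute_gate(img, txt, g).data.item())

        loss = compute_gate(img, txt, g)
        ad.backward(ad.sum_(loss))
        eps = 1e-6
        for name, t in g.tensors().items():
            grad = t.grad
            it = np.nditer(t.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = t.data[i]
                t.data[i] = old + eps
                up = loss_value()
                t.data[i] = old - eps
                dn = loss_value()
                t.data[i] = old
                num = (up - dn) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-9), name
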