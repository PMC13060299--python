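"""Transformer structure: permutation symmetry, attention normalisation,
Pre-LN residual identity, and equivalence with a loop-based attention oracle."""

import math

import numpy as np
import pytest

from cytoset._autodiff import Tensor
from cytoset.core import CytometrySample, MarkerVocabulary
from cytoset.model import (CytoTransformer, EncoderOutput, ModelConfig,
                           MultiHeadAttention)


def loop_attention(attn: MultiHeadAttention, query: np.ndarray, keyvalue: np.ndarray):
    """Straight-line scaled dot-product attention: explicit loops, no batching."""
    H, d = attn.heads, attn.head_dim
    wq, bq = attn.wq.w.data, attn.wq.b.data
    wk, bk = attn.wk.w.data, attn.wk.b.data
    wv, bv = attn.wv.w.data, attn.wv.b.data
    n_q, n = query.shape[0], keyvalue.shape[0]
    out_heads = np.zeros((n_q, H, d))
    for h in range(H):
        sl = slice(h * d, (h + 1) * d)
        for iq in range(n_q):
            q = query[iq] @ wq + bq
            scores = np.empty(n)
            for ik in range(n):
                k = keyvalue[ik] @ wk + bk
                scores[ik] = float(np.dot(q[sl], k[sl])) / math.sqrt(d)
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            ctx = np.zeros(d)
            for ik in range(n):
                v = keyvalue[ik] @ wv + bv
                ctx += w[ik] * v[sl]
            out_heads[iq, h] = ctx
    merged = out_heads.reshape(n_q, H * d)
    return merged @ attn.wo.w.data + attn.wo.b.data


@pytest.mark.parametrize("n,h,heads", [(1, 4, 2), (3, 8, 4), (8, 8, 2), (5, 6, 3)])
def test_attention_matches_loop_oracle(n, h, heads):
    rng = np.random.default_rng(n * 100 + h)
    attn = MultiHeadAttention(h, heads, rng)
    x = rng.normal(size=(n, h))
    mine = attn(Tensor(x), Tensor(x)).data
    np.testing.assert_allclose(mine, loop_attention(attn, x, x), atol=1e-6)


def test_cross_attention_matches_loop_oracle():
    rng = np.random.default_rng(0)
    attn = MultiHeadAttention(8, 4, rng)
    q, kv = rng.normal(size=(1, 8)), rng.normal(size=(6, 8))
    np.testing.assert_allclose(attn(Tensor(q), Tensor(kv)).data,
                               loop_attention(attn, q, kv), atol=1e-6)


class TestEncoder:
    def test_permutation_equivariance(self, tiny_model, sample):
        rng = np.random.default_rng(1)
        perm = rng.permutation(sample.n_cells)
        z = tiny_model.encode(sample).latent.data
        z_perm = tiny_model.encode(sample.permuted(perm)).latent.data
        np.testing.assert_allclose(z[perm], z_perm, atol=1e-10)

    def test_single_cell_finite(self, tiny_model, vocab):
        s = CytometrySample(np.array([[0.2, 0.4, 0.6]]), ["CD3", "CD8", "NK1.1"], "s")
        z = tiny_model.encode(s).latent.data
        assert z.shape == (1, 16) and np.all(np.isfinite(z))

    def test_duplicate_cells_identical_rows(self, tiny_model, vocab):
        events = np.vstack([np.full(3, 0.3), np.full(3, 0.3),
                            np.random.default_rng(0).normal(size=3)])
        s = CytometrySample(events, ["CD3", "CD8", "NK1.1"], "s")
        z = tiny_model.encode(s).latent.data
        np.testing.assert_allclose(z[0], z[1], atol=1e-12)

    def test_zeroed_blocks_are_residual_identity(self, vocab):
        config = ModelConfig(hidden_size=8, encoder_layers=3, decoder_layers=1, heads=2)
        model = CytoTransformer(vocab, config, seed=0)
        for block in model.encoder_blocks:
            for lin in (block.attn.wq, block.attn.wk, block.attn.wv, block.attn.wo,
                        block.ffn.fc1, block.ffn.fc2):
                lin.w.data[:] = 0.0
                lin.b.data[:] = 0.0
        x = np.random.default_rng(2).normal(size=(5, 8))
        out = x
        for block in model.encoder_blocks:
            out = block(Tensor(out)).data
        np.testing.assert_array_equal(out, x)

    def test_nonfinite_activation_reported_with_layer(self, tiny_model, sample):
        tiny_model.encoder_blocks[1].ffn.fc2.w.data[:] = np.inf
        with pytest.raises(FloatingPointError, match="encoder block 1"):
            tiny_model.encode(sample)


class TestDecoder:
    def test_prediction_invariant_attention_equivariant(self, tiny_model, sample):
        perm = np.random.default_rng(3).permutation(sample.n_cells)
        scores, amap = tiny_model.forward(sample)
        scores_p, amap_p = tiny_model.forward(sample.permuted(perm))
        np.testing.assert_allclose(scores.data, scores_p.data, atol=1e-10)
        np.testing.assert_allclose(amap.weights[:, :, perm], amap_p.weights, atol=1e-10)

    def test_single_cell_attention_is_one(self, tiny_model, vocab):
        s = CytometrySample(np.array([[0.2, 0.4, 0.6]]), ["CD3", "CD8", "NK1.1"], "s")
        _, amap = tiny_model.forward(s)
        np.testing.assert_array_equal(amap.weights, 1.0)

    def test_attention_rows_sum_to_one(self, tiny_model, sample):
        _, amap = tiny_model.forward(sample)
        np.testing.assert_allclose(amap.weights.sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(amap.per_layer_mean.sum(axis=-1), 1.0, atol=1e-6)

    def test_uniform_attention_expectation_7000_cells(self, vocab):
        # zeroed query/key projections force exactly uniform attention; with
        # 7000 cells every per-cell weight is 1/7000 ~ 1.4e-4
        config = ModelConfig(hidden_size=8, encoder_layers=0, decoder_layers=2, heads=2)
        model = CytoTransformer(vocab, config, seed=0)
        for block in model.decoder_blocks:
            block.attn.wq.w.data[:] = 0.0
            block.attn.wq.b.data[:] = 0.0
        n = 7000
        events = np.random.default_rng(0).normal(0.5, 0.2, size=(n, 3))
        s = CytometrySample(events, ["CD3", "CD8", "NK1.1"], "s")
        _, amap = model.forward(s)
        np.testing.assert_allclose(amap.weights, 1.0 / n, atol=1e-12)
        assert 1.0 / n == pytest.approx(1.4e-4, rel=0.03)


class TestPretrainHeads:
    def test_variances_strictly_positive_and_shaped(self, tiny_model, sample, vocab):
        out = tiny_model.pretrain_heads(tiny_model.encode(sample))
        for t in (out.expr_var, out.pct_var, out.dens_var):
            assert t.shape == (sample.n_cells, vocab.size)
            assert np.all(t.data > 0)
        assert out.expr_mean.shape == (sample.n_cells, vocab.size)

    def test_per_cell_independence(self, tiny_model, sample):
        latent = tiny_model.encode(sample).latent.data.copy()
        base = tiny_model.pretrain_heads(EncoderOutput(Tensor(latent))).expr_mean.data
        latent2 = latent.copy()
        latent2[4] += 10.0
        edited = tiny_model.pretrain_heads(EncoderOutput(Tensor(latent2))).expr_mean.data
        mask = np.ones(sample.n_cells, dtype=bool)
        mask[4] = False
        np.testing.assert_array_equal(base[mask], edited[mask])
        assert not np.array_equal(base[4], edited[4])

    def test_variance_floor_counted(self, tiny_model, sample):
        tiny_model.heads["expression"].logvar.w.data[:] = 0.0
        tiny_model.heads["expression"].logvar.b.data[:] = -100.0  # exp -> ~0
        out = tiny_model.pretrain_heads(tiny_model.encode(sample))
        assert np.all(out.expr_var.data >= 1e-6)
        assert out.clamped_entries >= sample.n_cells


def test_checkpoint_roundtrip(tmp_path, tiny_model, sample):
    tiny_model.latent_mu = np.random.default_rng(0).normal(size=16)
    scores, _ = tiny_model.forward(sample)
    path = tmp_path / "model.ckpt"
    tiny_model.save(path)
    loaded = CytoTransformer.load(path)
    scores2, _ = loaded.forward(sample)
    np.testing.assert_array_equal(scores.data, scores2.data)
    assert loaded.vocabulary.markers == tiny_model.vocabulary.markers


def test_hidden_size_must_divide_heads():
    with pytest.raises(ValueError):
        ModelConfig(hidden_size=10, heads=4)
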