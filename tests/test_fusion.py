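"""Fusion oracles: factorised LMF vs dense tensor contraction, attention
closed forms, transformer-block degenerate cases, and joint trainability."""

import numpy as np
import pytest

from copdfusion.autodiff import Tensor, no_grad
from copdfusion.fusion import (CrossModalBlock, FusionConfig, FusionHead,
                               LMF, MultiModalClassifier, lmf_fuse,
                               reconstruct_weight_tensor,
                               scaled_dot_attention, tensor_fusion_oracle)
from copdfusion.layers import cross_entropy


def random_factors(rng, dims, d_h, r):
    return [rng.normal(size=(r, d_h, d)) for d in dims]


class TestLMF:
    def test_all_ones_rank1_scalar_output(self):
        za, zv = np.array([1.0, 2.0, 3.0]), np.array([4.0, -1.0])
        factors = [np.ones((1, 1, 3)), np.ones((1, 1, 2))]
        h = lmf_fuse([za, zv], factors)
        assert h[0] == pytest.approx(za.sum() * zv.sum())

    def test_zero_modality_annihilates(self, rng):
        factors = random_factors(rng, [3, 4], d_h=2, r=2)
        h = lmf_fuse([np.zeros(3), rng.normal(size=4)], factors)
        assert np.allclose(h, 0.0)

    def test_equivalence_with_dense_oracle(self, rng):
        for _ in range(30):
            m = rng.integers(2, 4)
            dims = rng.integers(1, 6, size=m)
            d_h, r = int(rng.integers(1, 5)), int(rng.integers(1, 4))
            factors = random_factors(rng, dims, d_h, r)
            z = [rng.normal(size=d) for d in dims]
            w = reconstruct_weight_tensor(factors)
            assert np.allclose(lmf_fuse(z, factors),
                               tensor_fusion_oracle(w, z), atol=1e-8)

    def test_module_matches_functional(self, rng):
        lmf = LMF([3, 4], d_h=2, rank=2, rng=np.random.default_rng(0))
        za, zv = rng.normal(size=(5, 3)), rng.normal(size=(5, 4))
        with no_grad():
            h = lmf([Tensor(za), Tensor(zv)]).data
        factors = [f.data for f in lmf.factors]
        for i in range(5):
            assert np.allclose(h[i], lmf_fuse([za[i], zv[i]], factors),
                               atol=1e-10)

    def test_rank_and_dim_validation(self, rng):
        with pytest.raises(ValueError, match="rank"):
            LMF([3, 4], d_h=2, rank=0, rng=np.random.default_rng(0))
        factors = random_factors(rng, [3, 4], 2, 1)
        with pytest.raises(ValueError, match="dim"):
            lmf_fuse([np.zeros(5), np.zeros(4)], factors)


class TestWeightTensor:
    def test_rank1_outer_product(self, rng):
        factors = random_factors(rng, [3, 4], d_h=2, r=1)
        w = reconstruct_weight_tensor(factors)
        assert w.shape == (2, 3, 4)
        for k in range(2):
            expected = np.outer(factors[0][0, k], factors[1][0, k])
            assert np.allclose(w[k], expected)
            assert np.linalg.matrix_rank(w[k]) <= 1

    def test_zero_factors_zero_tensor(self):
        factors = [np.zeros((2, 3, 4)), np.zeros((2, 3, 5))]
        assert np.allclose(reconstruct_weight_tensor(factors), 0.0)

    def test_rank_bound(self, rng):
        factors = random_factors(rng, [4, 5], d_h=3, r=2)
        w = reconstruct_weight_tensor(factors)
        for k in range(3):
            assert np.linalg.matrix_rank(w[k]) <= 2

    def test_oracle_unfolding_identity(self, rng):
        # W[k] = indicator of the k-th (i, j) pair -> h = vec(za (x) zv)
        da, dv = 2, 3
        w = np.zeros((da * dv, da, dv))
        for k in range(da * dv):
            w[k, k // dv, k % dv] = 1.0
        za, zv = rng.normal(size=da), rng.normal(size=dv)
        h = tensor_fusion_oracle(w, [za, zv])
        assert np.allclose(h, np.outer(za, zv).ravel())

    def test_oracle_zero_weight(self, rng):
        h = tensor_fusion_oracle(np.zeros((2, 3, 4)),
                                 [rng.normal(size=3), rng.normal(size=4)])
        assert np.allclose(h, 0.0)


class TestAttention:
    def test_single_key_returns_value_row(self, rng):
        q = rng.normal(size=(4, 3))
        k = rng.normal(size=(1, 3))
        v = rng.normal(size=(1, 5))
        out = scaled_dot_attention(q, k, v).data
        assert np.allclose(out, np.tile(v, (4, 1)), atol=1e-12)

    def test_identical_keys_give_value_mean(self, rng):
        q = rng.normal(size=(3, 2))
        k = np.tile(rng.normal(size=(1, 2)), (6, 1))
        v = rng.normal(size=(6, 4))
        out = scaled_dot_attention(q, k, v).data
        assert np.allclose(out, np.tile(v.mean(0), (3, 1)), atol=1e-12)

    def test_hand_example_two_by_two(self):
        q = k = np.eye(2)
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = scaled_dot_attention(q, k, v).data
        e = np.exp(1.0 / np.sqrt(2.0))
        w_same = e / (e + 1.0)
        expected = np.array([[w_same, 1 - w_same], [1 - w_same, w_same]])
        assert np.allclose(out, expected, atol=1e-9)

    def test_rows_sum_to_one_and_convex_hull(self, rng):
        q = rng.normal(size=(5, 3))
        k = rng.normal(size=(7, 3))
        v = rng.normal(size=(7, 2))
        scores = (q @ k.T) / np.sqrt(3)
        w = np.exp(scores - scores.max(1, keepdims=True))
        w /= w.sum(1, keepdims=True)
        assert np.allclose(w.sum(1), 1.0, atol=1e-9)
        out = scaled_dot_attention(q, k, v).data
        assert out.min() >= v.min() - 1e-9
        assert out.max() <= v.max() + 1e-9

    def test_empty_key_dimension_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 0)), np.zeros((2, 0)),
                                 np.zeros((2, 3)))


class TestCrossModalBlock:
    def make_block(self, d_model=4, heads=2, seed=0):
        return CrossModalBlock(d_model, heads, np.random.default_rng(seed))

    def test_zero_output_projections_give_identity(self, rng):
        block = self.make_block()
        block.attn.wo.weight.data[:] = 0.0
        block.attn.wo.bias.data[:] = 0.0
        block.ffn_out.weight.data[:] = 0.0
        block.ffn_out.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 3, 4)))
        src = Tensor(rng.normal(size=(2, 5, 4)))
        with no_grad():
            out = block(x, src)
        assert np.allclose(out.data, x.data, atol=1e-12)

    def test_output_length_matches_target_for_any_source_length(self, rng):
        block = self.make_block()
        x = Tensor(rng.normal(size=(2, 3, 4)))
        for src_len in (1, 2, 9):
            src = Tensor(rng.normal(size=(2, src_len, 4)))
            with no_grad():
                out = block(x, src)
            assert out.shape == (2, 3, 4)

    def test_single_source_token_attention_is_projected_source(self, rng):
        """With one key, attention output per token is the projected source
        token regardless of the query."""
        block = self.make_block()
        x = Tensor(rng.normal(size=(1, 3, 4)))
        src = Tensor(rng.normal(size=(1, 1, 4)))
        with no_grad():
            ln_s = block.ln_source(src)
            v = block.attn.wv(ln_s)
            proj = block.attn.wo(v)
            att = block.attn(block.ln_target(x), ln_s)
        assert np.allclose(att.data, np.tile(proj.data, (1, 3, 1)),
                           atol=1e-10)

    def test_forward_matches_composed_sub_operations(self, rng):
        """Layer-by-layer oracle of the pre-norm block at d_model=2."""
        block = self.make_block(d_model=2, heads=1, seed=1)
        x = rng.normal(size=(1, 2, 2))
        src = rng.normal(size=(1, 2, 2))
        with no_grad():
            out = block(Tensor(x), Tensor(src)).data
            lt = block.ln_target(Tensor(x)).data
            ls = block.ln_source(Tensor(src)).data
            q = lt @ block.attn.wq.weight.data + block.attn.wq.bias.data
            k = ls @ block.attn.wk.weight.data + block.attn.wk.bias.data
            v = ls @ block.attn.wv.weight.data + block.attn.wv.bias.data
            scores = q @ k.transpose(0, 2, 1) / np.sqrt(2.0)
            w = np.exp(scores - scores.max(-1, keepdims=True))
            w /= w.sum(-1, keepdims=True)
            att = (w @ v) @ block.attn.wo.weight.data + block.attn.wo.bias.data
            u = x + att
            lu = block.ln_ffn(Tensor(u)).data
            ff = np.maximum(lu @ block.ffn_in.weight.data
                            + block.ffn_in.bias.data, 0.0)
            expected = u + ff @ block.ffn_out.weight.data \
                + block.ffn_out.bias.data
        assert np.allclose(out, expected, atol=1e-9)


class TestFusionHead:
    def test_eval_determinism_and_dims(self, rng):
        head = FusionHead(64, 64, FusionConfig(seed=0))
        za = Tensor(rng.normal(size=(3, 64)))
        zv = Tensor(rng.normal(size=(3, 64)))
        head.eval()
        with no_grad():
            f1, l1 = head(za, zv)
            f2, l2 = head(za, zv)
        assert np.array_equal(l1.data, l2.data)
        assert f1.shape == (3, 2 * head.config.d_model)
        assert l1.shape == (3, 2)

    def test_gradient_reaches_every_component(self, rng):
        """Joint trainability: a generic batch sends finite, nonzero
        gradient into the PB branch, CT branch and fusion head."""
        from copdfusion.ct import ResNetLite3D
        from copdfusion.gnn import GNNConfig, PBGraphNet
        from copdfusion.graph import FeatureGraph

        graph = FeatureGraph(5, [(0, 1), (1, 2), (3, 4)], [1.0] * 3)
        pb = PBGraphNet(graph, GNNConfig(hidden_dim=4, out_dim=8, seed=0,
                                         dropout=0.0))
        ct = ResNetLite3D(out_dim=8, seed=0, channels=(2, 4, 8))
        head = FusionHead(8, 8, FusionConfig(d_h=8, rank=2, n_tokens=2,
                                             d_model=4, heads=2, seed=0))
        model = MultiModalClassifier(pb, ct, head)
        x_pb = rng.normal(size=(4, 5))
        x_ct = rng.random((4, 8, 16, 16)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        _, logits = model(x_pb, x_ct)
        loss = cross_entropy(logits, y)
        loss.backward()
        for comp_name, comp in [("pb", pb), ("ct", ct), ("head", head)]:
            total = 0.0
            for name, p in comp.named_parameters():
                if name.startswith("clf."):
                    # the branches' own classification heads serve only the
                    # unimodal pretraining task; the fused loss bypasses them
                    continue
                assert p.grad is not None, f"{comp_name}.{name} missing grad"
                assert np.isfinite(p.grad).all(), f"{comp_name}.{name} grad"
                total += float(np.abs(p.grad).sum())
            assert total > 0.0, f"no gradient reached {comp_name}"

    def test_swap_query_config_changes_output(self, rng):
        za = Tensor(rng.normal(size=(2, 64)))
        zv = Tensor(rng.normal(size=(2, 64)))
        out = []
        for swap in (False, True):
            head = FusionHead(64, 64, FusionConfig(seed=0, swap_query=swap))
            head.eval()
            with no_grad():
                out.append(head(za, zv)[1].data)
        assert not np.allclose(out[0], out[1])
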