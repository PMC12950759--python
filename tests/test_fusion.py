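"""Cross-attention fusion: scaled dot-product attention, per-head
bidirectional cross-attention, residual LayerNorm, FFN fusion, supervised
contrastive loss, baseline fusers and joint training."""

import numpy as np
import pytest

from momhca import (
    AttentionConfig,
    ContrastiveConfig,
    MHCAFusion,
    attention_weights,
    baseline_fuse,
    cross_attention_heads,
    fuse,
    residual_layernorm,
    scaled_dot_attention,
    supervised_contrastive_loss,
    train_fusion,
)
from momhca.fusion import FusionFFNConfig, init_attention_params, _contrastive_loss_t
from momhca import nn


class TestScaledDotAttention:
    def test_single_key_returns_value(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 5))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V, (4, 1)))

    def test_identical_keys_average_values(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(3, 2))
        K = np.tile(rng.normal(size=(1, 2)), (4, 1))
        V = rng.normal(size=(4, 2))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (3, 1)), atol=1e-12)

    def test_two_key_scalar_oracle(self):
        Q, K, V = np.array([[1.0]]), np.array([[1.0], [0.0]]), np.array([[2.0], [0.0]])
        w1 = np.e / (np.e + 1.0)  # d_k = 1 so no scaling effect
        expected = w1 * 2.0
        assert scaled_dot_attention(Q, K, V)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_kv_rows_error(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 2)), np.ones((3, 2)), np.ones((2, 2)))


class TestCrossAttentionHeads:
    def test_symmetric_inputs_and_shared_projections_give_equal_heads(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(5, 8))
        cfg = AttentionConfig(n_heads=2, model_dim=8)
        params = init_attention_params(cfg, rng)
        params["j"] = params["i"]
        hi, hj = cross_attention_heads(Z, Z, params, cfg)
        assert np.allclose(hi, hj)

    def test_single_head_reduces_to_plain_attention_plus_projection(self):
        rng = np.random.default_rng(3)
        Zi, Zj = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        cfg = AttentionConfig(n_heads=1, model_dim=6)
        params = init_attention_params(cfg, rng)
        hi, _ = cross_attention_heads(Zi, Zj, params, cfg)
        p = params["i"]
        expected = scaled_dot_attention(Zi @ p["Wq"][0], Zj @ p["Wk"][0],
                                        Zj @ p["Wv"][0]) @ p["Wo"]
        assert np.allclose(hi, expected, atol=1e-12)

    def test_matches_per_head_loop_oracle(self):
        rng = np.random.default_rng(4)
        Zi, Zj = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        cfg = AttentionConfig(n_heads=2, model_dim=4)
        params = init_attention_params(cfg, rng)
        hi, hj = cross_attention_heads(Zi, Zj, params, cfg)
        for got, Zq, Zkv, p in ((hi, Zi, Zj, params["i"]), (hj, Zj, Zi, params["j"])):
            heads = []
            for h in range(2):
                Q, K, V = Zq @ p["Wq"][h], Zkv @ p["Wk"][h], Zkv @ p["Wv"][h]
                S = np.zeros((3, 3))
                for a in range(3):
                    for b in range(3):
                        S[a, b] = Q[a] @ K[b] / np.sqrt(2)
                W = np.exp(S) / np.exp(S).sum(axis=1, keepdims=True)
                heads.append(W @ V)
            assert np.allclose(got, np.concatenate(heads, axis=1) @ p["Wo"], atol=1e-6)

    def test_attention_weights_row_stochastic_per_head(self):
        rng = np.random.default_rng(5)
        Zi, Zj = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        cfg = AttentionConfig(n_heads=4, model_dim=8)
        params = init_attention_params(cfg, rng)
        for mats in attention_weights(Zi, Zj, params).values():
            assert len(mats) == 4
            for W in mats:
                assert np.all(W >= 0)
                assert np.allclose(W.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        Zi, Zj = rng.normal(size=(7, 4)), rng.normal(size=(7, 4))
        cfg = AttentionConfig(n_heads=2, model_dim=4)
        params = init_attention_params(cfg, rng)
        perm = rng.permutation(7)
        hi, hj = cross_attention_heads(Zi, Zj, params, cfg)
        pi, pj = cross_attention_heads(Zi[perm], Zj[perm], params, cfg)
        assert np.allclose(pi, hi[perm], atol=1e-10)
        assert np.allclose(pj, hj[perm], atol=1e-10)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            cross_attention_heads(np.ones((3, 4)), np.ones((4, 4)))


class TestResidualLayerNorm:
    def test_head_cancelling_z_gives_bias_rows(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(3, 5))
        bias = rng.normal(size=5)
        out = residual_layernorm(-Z, Z, gain=np.ones(5), bias=bias)
        assert np.allclose(out, np.tile(bias, (3, 1)), atol=1e-10)

    def test_row_mean_zero_with_unit_gain(self):
        rng = np.random.default_rng(8)
        out = residual_layernorm(rng.normal(size=(4, 8)), rng.normal(size=(4, 8)))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(out.std(axis=1), 1.0, atol=1e-3)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        head, Z = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        out = residual_layernorm(head, Z)
        for r in range(4):
            x = head[r] + Z[r]
            expected = (x - x.mean()) / np.sqrt(x.var() + 1e-5)
            assert np.allclose(out[r], expected, atol=1e-10)


class TestFuse:
    def test_zero_inputs_zero_weights_give_bias_rows(self):
        d = 3
        b2 = np.array([1.0, -2.0, 0.5])
        out = fuse(np.zeros((4, d)), np.zeros((4, d)),
                   W1=np.zeros((2 * d, 5)), b1=np.zeros(5),
                   W2=np.zeros((5, d)), b2=b2)
        assert np.allclose(out, np.tile(b2, (4, 1)))

    def test_concatenation_order_matters(self):
        rng = np.random.default_rng(10)
        hi, hj = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        W1, b1 = rng.normal(size=(4, 6)), rng.normal(size=6)
        W2, b2 = rng.normal(size=(6, 2)), rng.normal(size=2)
        a = fuse(hi, hj, W1, b1, W2, b2)
        b = fuse(hj, hi, W1, b1, W2, b2)
        assert not np.allclose(a, b)

    def test_identity_block_weights_hand_oracle(self):
        hi = np.array([[1.0, 2.0], [0.0, -1.0]])
        hj = np.array([[3.0, 0.0], [1.0, 1.0]])
        # W1 stacks [I; I] so hidden = relu(hi + hj); W2 = I
        W1 = np.vstack([np.eye(2), np.eye(2)])
        out = fuse(hi, hj, W1, np.zeros(2), np.eye(2), np.zeros(2))
        assert np.allclose(out, np.maximum(hi + hj, 0.0))


class TestSupervisedContrastive:
    def test_closed_form_one_positive_three_orthogonal_negatives(self):
        # anchor/positive aligned (cos 1), negatives orthogonal (cos 0), τ=0.5
        Z = np.array([[1.0, 0, 0, 0, 0],
                      [1.0, 0, 0, 0, 0],
                      [0, 1.0, 0, 0, 0],
                      [0, 0, 1.0, 0, 0],
                      [0, 0, 0, 1.0, 0]])
        labels = np.array([0, 0, 1, 2, 3])
        cfg = ContrastiveConfig(temperature=0.5)
        loss = supervised_contrastive_loss(Z, labels, cfg)
        pair_term = -np.log(np.e ** 2 / (np.e ** 2 + 3.0))
        # anchors 0 and 1 contribute the identical closed-form term; the
        # singleton-class anchors have no positives
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert loss == pytest.approx(pair_term, abs=1e-6)

    def test_raising_negative_similarity_increases_loss(self):
        base = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        lo = supervised_contrastive_loss(base, labels)
        closer = base.copy()
        closer[2] = np.array([0.5, 1.0]) / np.linalg.norm([0.5, 1.0])
        hi = supervised_contrastive_loss(closer, labels)
        assert hi > lo

    def test_invariant_to_orthogonal_rotation(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(12, 6))
        labels = np.repeat([0, 1, 2], 4)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = supervised_contrastive_loss(Z, labels)
        b = supervised_contrastive_loss(Z @ Q, labels)
        assert a == pytest.approx(b, abs=1e-10)

    def test_structured_embeddings_beat_shuffled(self):
        rng = np.random.default_rng(12)
        Z = np.repeat(np.eye(2), 6, axis=0)  # two orthogonal one-hot classes
        labels = np.repeat([0, 1], 6)
        structured = supervised_contrastive_loss(Z, labels)
        shuffled_losses = []
        for _ in range(20):
            perm = rng.permutation(12)
            shuffled_losses.append(supervised_contrastive_loss(Z[perm], labels))
        assert structured < np.mean(shuffled_losses)

    def test_invalid_inputs_error(self):
        Z = np.eye(3)
        with pytest.raises(ValueError, match="temperature"):
            ContrastiveConfig(temperature=0.0)
        with pytest.raises(ValueError, match="two classes"):
            supervised_contrastive_loss(Z, np.zeros(3))

    def test_trainer_term_is_zero_without_negatives(self):
        # single class inside the training subset: every pair term is −log 1
        Z = nn.Tensor(np.random.default_rng(13).normal(size=(4, 3)))
        loss = _contrastive_loss_t(Z, np.zeros(4, dtype=int), temperature=0.5)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_trainer_term_matches_reference_implementation(self):
        rng = np.random.default_rng(14)
        Z = rng.normal(size=(10, 5))
        labels = np.repeat([0, 1], 5)
        ref = supervised_contrastive_loss(Z, labels, ContrastiveConfig(temperature=0.5))
        got = float(_contrastive_loss_t(nn.Tensor(Z), labels, 0.5).data)
        assert got == pytest.approx(ref, abs=1e-10)


class TestBaselineFuse:
    def test_sum_with_zero_second_input_is_identity(self):
        rng = np.random.default_rng(15)
        Z = rng.normal(size=(4, 3))
        assert np.allclose(baseline_fuse(Z, np.zeros_like(Z), "sum"), Z)

    def test_average_of_identical_inputs_is_input(self):
        rng = np.random.default_rng(16)
        Z = rng.normal(size=(4, 3))
        assert np.allclose(baseline_fuse(Z, Z, "average"), Z)

    def test_concat_projects_back_to_d(self):
        rng = np.random.default_rng(17)
        Zi, Zj = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        out = baseline_fuse(Zi, Zj, "concat", seed=0)
        assert out.shape == (5, 4)
        P = np.random.default_rng(0).uniform(
            -np.sqrt(6 / 12), np.sqrt(6 / 12), size=(8, 4))
        assert np.allclose(out, np.concatenate([Zi, Zj], axis=1) @ P)

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            baseline_fuse(np.ones((2, 2)), np.ones((2, 2)), "magic")


class TestMHCAModule:
    def test_module_forward_matches_stateless_functions(self):
        """The trainable module and the stateless reference path compute the
        same fused embedding from the same weights."""
        rng = np.random.default_rng(18)
        Zi, Zj = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        attn = AttentionConfig(n_heads=2, model_dim=8)
        model = MHCAFusion(attn, FusionFFNConfig(hidden_dim=6, output_dim=8),
                           np.random.default_rng(19))
        hi_t, hj_t, fused_t = model.forward(nn.Tensor(Zi), nn.Tensor(Zj))

        params = model.numpy_params()
        hi, hj = cross_attention_heads(Zi, Zj, params, attn)
        hi = residual_layernorm(hi, Zi, model.ln_gain["i"].data, model.ln_bias["i"].data)
        hj = residual_layernorm(hj, Zj, model.ln_gain["j"].data, model.ln_bias["j"].data)
        fused = fuse(hi, hj, model.ffn1.W.data, model.ffn1.b.data,
                     model.ffn2.W.data, model.ffn2.b.data)
        assert np.allclose(hi_t.data, hi, atol=1e-10)
        assert np.allclose(hj_t.data, hj, atol=1e-10)
        assert np.allclose(fused_t.data, fused, atol=1e-10)


class TestTrainFusion:
    def test_lambda_zero_reduces_to_reconstruction_only(self, tiny_latents):
        Zi, Zj, labels = tiny_latents
        mask = np.ones(len(labels), dtype=bool)
        _, _, hist = train_fusion(Zi, Zj, labels, mask,
                                  con_cfg=ContrastiveConfig(loss_weight=0.0),
                                  epochs=5, seed=0)
        assert hist["contrastive"] == [0.0] * 5
        assert np.allclose(hist["total"], hist["recon"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_contrastive_term_decreases(self, seed, tiny_latents):
        Zi, Zj, labels = tiny_latents
        mask = np.ones(len(labels), dtype=bool)
        _, _, hist = train_fusion(Zi, Zj, labels, mask, epochs=30, seed=seed)
        assert hist["contrastive"][-1] <= hist["contrastive"][0]

    def test_empty_train_mask_errors(self, tiny_latents):
        Zi, Zj, labels = tiny_latents
        with pytest.raises(ValueError, match="empty"):
            train_fusion(Zi, Zj, labels, np.zeros(len(labels), dtype=bool))

    def test_test_labels_never_read(self, tiny_latents):
        """Scrambling labels outside the train mask leaves training
        bit-identical."""
        Zi, Zj, labels = tiny_latents
        mask = np.zeros(len(labels), dtype=bool)
        mask[::2] = True
        _, fused_a, _ = train_fusion(Zi, Zj, labels, mask, epochs=5, seed=0)
        scrambled = labels.copy()
        scrambled[~mask] = -1
        _, fused_b, _ = train_fusion(Zi, Zj, scrambled, mask, epochs=5, seed=0)
        assert np.array_equal(fused_a, fused_b)

    def test_separable_types_recovered_by_kmeans(self, tiny_latents):
        from momhca import clustering_metrics, kmeans_cluster

        Zi, Zj, labels = tiny_latents
        mask = np.ones(len(labels), dtype=bool)
        ok = 0
        for seed in (0, 1, 2):
            _, fused, _ = train_fusion(Zi, Zj, labels, mask, epochs=40, seed=seed)
            km = kmeans_cluster(fused, 3, seed=seed)
            ari, _, _ = clustering_metrics(labels, km)
            ok += ari >= 0.9
        assert ok == 3
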