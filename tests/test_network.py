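"""Network mathematics: extraction, attention, fusion, prediction head."""

import math

import numpy as np
import pytest

from plmppi.network import (AttentionParams, ModelConfig, PairClassifier,
                            feature_extract, fuse_pair, multi_head_attention,
                            predict_pair, self_attention)


def loop_attention(x, wq, wk, wv):
    """Explicit-loop evaluation of softmax(QK^T/sqrt(d_k))V."""
    q, k, v = x @ wq, x @ wk, x @ wv
    t, dk = q.shape
    weights = np.zeros((t, t))
    for i in range(t):
        scores = [sum(q[i, d] * k[j, d] for d in range(dk)) / math.sqrt(dk)
                  for j in range(t)]
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        weights[i] = [e / sum(exps) for e in exps]
    out = np.zeros((t, dk))
    for i in range(t):
        for d in range(dk):
            out[i, d] = sum(weights[i, j] * v[j, d] for j in range(t))
    return out, weights


class TestFeatureExtract:
    def test_identity_weights_pass_nonnegative_input(self):
        v = np.array([0.5, 1.0, 2.0])
        out = feature_extract(v, np.eye(3), np.zeros(3))
        assert np.array_equal(out, v)

    def test_negative_entries_threshold_to_zero(self):
        out = feature_extract(np.array([1.0, -2.0, 3.0]), np.eye(3), np.zeros(3))
        assert np.array_equal(out, [1.0, 0.0, 3.0])

    def test_hand_computed_affine_relu(self):
        w = np.array([[1.0, 0.0], [2.0, -1.0], [0.0, 3.0]])  # (in=3, out=2)
        b = np.array([0.5, -4.0])
        v = np.array([1.0, 2.0, 1.0])
        # z = [1+4+0+0.5, 0-2+3-4] = [5.5, -3.0] -> relu -> [5.5, 0]
        out = feature_extract(v, w, b)
        assert np.allclose(out, [5.5, 0.0], atol=1e-12)

    def test_shared_weights_have_no_pair_order_dependence(self, rng):
        w, b = rng.standard_normal((8, 4)), rng.standard_normal(4)
        v1, v2 = rng.standard_normal(8), rng.standard_normal(8)
        a = (feature_extract(v1, w, b), feature_extract(v2, w, b))
        b_ = (feature_extract(v2, w, b), feature_extract(v1, w, b))
        assert np.array_equal(a[0], b_[1]) and np.array_equal(a[1], b_[0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            feature_extract(np.zeros(3), np.eye(4), np.zeros(4))


class TestSelfAttention:
    def test_single_token_weight_is_one(self, rng):
        p = AttentionParams(*(rng.standard_normal((3, 2)) for _ in range(3)))
        res = self_attention(rng.standard_normal((1, 3)), p)
        assert np.allclose(res.weights, [[1.0]])
        x = rng.standard_normal((1, 3))
        res = self_attention(x, p)
        assert np.allclose(res.output, x @ p.w_v.data if hasattr(p.w_v, "data")
                           else x @ p.w_v, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(5):
            t, d, dk = rng.integers(1, 6), rng.integers(1, 6), rng.integers(1, 6)
            p = AttentionParams(*(rng.standard_normal((d, dk)) for _ in range(3)))
            res = self_attention(rng.standard_normal((t, d)), p)
            assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)
            assert (res.weights >= 0).all()

    def test_matches_explicit_loop_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal((2, 2))
            mats = [rng.standard_normal((2, 2)) for _ in range(3)]
            p = AttentionParams(*mats)
            res = self_attention(x, p)
            out, w = loop_attention(x, *mats)
            assert np.max(np.abs(res.output - out)) < 1e-10
            assert np.max(np.abs(res.weights - w)) < 1e-10

    def test_zero_projections_give_zero_output_uniform_weights(self):
        p = AttentionParams(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros((3, 2)))
        res = self_attention(np.ones((4, 3)), p)
        assert not res.output.any()
        assert np.allclose(res.weights, 0.25)

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((5, 3))
        p = AttentionParams(*(rng.standard_normal((3, 3)) for _ in range(3)))
        perm = rng.permutation(5)
        base = self_attention(x, p)
        permed = self_attention(x[perm], p)
        assert np.allclose(permed.output, base.output[perm], atol=1e-12)
        assert np.allclose(permed.weights, base.weights[np.ix_(perm, perm)],
                           atol=1e-12)


class TestMultiHeadAttention:
    def test_one_head_with_identity_output_equals_self_attention(self, rng):
        mats = [rng.standard_normal((4, 4)) for _ in range(3)]
        x = rng.standard_normal((3, 4))
        mha = multi_head_attention(x, [AttentionParams(*mats)], np.eye(4))
        single = self_attention(x, AttentionParams(*mats)).output
        assert np.allclose(mha, single, atol=1e-12)

    @pytest.mark.parametrize("n_heads", [1, 2, 4])
    def test_output_shape_preserved(self, n_heads, rng):
        d, t = 8, 3
        dk = d // n_heads
        heads = [AttentionParams(*(rng.standard_normal((d, dk))
                                   for _ in range(3))) for _ in range(n_heads)]
        out = multi_head_attention(rng.standard_normal((t, d)), heads,
                                   rng.standard_normal((d, d)))
        assert out.shape == (t, d)

    def test_two_heads_match_per_head_oracle(self, rng):
        d, dk = 4, 2
        x = rng.standard_normal((2, d))
        head_mats = [[rng.standard_normal((d, dk)) for _ in range(3)]
                     for _ in range(2)]
        w_out = rng.standard_normal((d, d))
        got = multi_head_attention(x, [AttentionParams(*m) for m in head_mats],
                                   w_out)
        parts = [loop_attention(x, *m)[0] for m in head_mats]
        expected = np.concatenate(parts, axis=1) @ w_out
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_indivisible_heads_rejected(self, rng):
        heads = [AttentionParams(*(rng.standard_normal((4, 1))
                                   for _ in range(3))) for _ in range(3)]
        with pytest.raises(ValueError, match="divide"):
            multi_head_attention(np.zeros((2, 4)), heads, np.eye(4))


class TestFusePair:
    @staticmethod
    def identity_params(d):
        return AttentionParams(np.eye(d), np.eye(d), np.eye(d))

    def test_equal_features_give_f2_equal_to_f1_vec(self, rng):
        f = rng.standard_normal(4)
        out = fuse_pair(f, f, self.identity_params(4))
        assert np.allclose(out.F2, f, atol=1e-12)

    def test_f2_invariant_under_pair_swap(self, rng):
        p = AttentionParams(*(rng.standard_normal((4, 4)) for _ in range(3)))
        f1, f2 = rng.standard_normal(4), rng.standard_normal(4)
        assert np.allclose(fuse_pair(f1, f2, p).F2, fuse_pair(f2, f1, p).F2,
                           atol=1e-12)

    def test_concatenation_length(self, rng):
        p = AttentionParams(*(rng.standard_normal((6, 6)) for _ in range(3)))
        out = fuse_pair(rng.standard_normal(6), rng.standard_normal(6), p)
        assert len(out.F) == len(out.F1) + len(out.F2) == 2 * 6 + 6

    def test_hand_worked_two_dim_example(self):
        # f1 = (1, 2), f2 = (3, 4), identity projections, d_k = 2
        f1, f2 = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        out = fuse_pair(f1, f2, self.identity_params(2))
        x = np.stack([f1, f2])
        s = x @ x.T / math.sqrt(2)  # raw attention scores
        w = np.exp(s - s.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        F1 = (w @ x).ravel()
        assert np.max(np.abs(out.F1 - F1)) < 1e-10
        assert np.allclose(out.F2, [2.0, 3.0], atol=1e-12)
        assert np.max(np.abs(out.F - np.concatenate([F1, [2.0, 3.0]]))) < 1e-10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            fuse_pair(np.zeros(3), np.zeros(4), self.identity_params(3))


class TestPredictPair:
    def test_zero_logit_gives_half(self):
        layers = [(np.zeros((4, 1)), np.zeros(1))]
        assert predict_pair(np.ones(4), layers) == pytest.approx(0.5)

    def test_bias_monotonicity(self, rng):
        w = rng.standard_normal((4, 1))
        f = rng.standard_normal(4)
        probs = [predict_pair(f, [(w, np.array([b]))]) for b in (-1.0, 0.0, 1.0)]
        assert probs[0] < probs[1] < probs[2]

    def test_two_layer_hand_forward(self):
        w1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.0, -1.0])
        w2 = np.array([[2.0], [1.0]])
        b2 = np.array([-0.5])
        f = np.array([2.0, 1.0])
        h = np.maximum(f @ w1 + b1, 0)          # [2.5, 0.0]
        logit = (h @ w2 + b2).item()            # 4.5
        expected = 1 / (1 + math.exp(-logit))
        assert predict_pair(f, [(w1, b1), (w2, b2)]) == pytest.approx(
            expected, abs=1e-10)

    def test_output_strictly_inside_unit_interval(self, rng):
        layers = [(rng.standard_normal((6, 3)), rng.standard_normal(3)),
                  (rng.standard_normal((3, 1)), rng.standard_normal(1))]
        p = predict_pair(rng.standard_normal(6), layers)
        assert 0.0 < p < 1.0

    def test_nonfinite_intermediate_names_layer(self):
        layers = [(np.full((2, 2), 1e200), np.zeros(2)),
                  (np.full((2, 1), 1e200), np.zeros(1))]
        with np.errstate(over="ignore"), \
                pytest.raises(FloatingPointError, match="layer 1"):
            predict_pair(np.array([1.0, 1.0]), layers)


class TestPairClassifier:
    CFG = dict(input_dim=32, extractor_dim=8, head_layers=(8, 1), n_heads=2,
               dropout_rate=0.2, seed=3)

    def test_evaluation_mode_is_bitwise_deterministic(self, rng):
        model = PairClassifier(ModelConfig(**self.CFG))
        x1, x2 = rng.standard_normal((5, 32)), rng.standard_normal((5, 32))
        a = model.predict_proba(x1, x2)
        b = model.predict_proba(x1, x2)
        assert a.tobytes() == b.tobytes()

    def test_save_load_round_trip(self, rng, tmp_path):
        model = PairClassifier(ModelConfig(**self.CFG))
        x1, x2 = rng.standard_normal((4, 32)), rng.standard_normal((4, 32))
        model.save(tmp_path / "m.npz")
        clone = PairClassifier.load(tmp_path / "m.npz")
        assert clone.config == model.config
        assert np.array_equal(clone.predict_proba(x1, x2),
                              model.predict_proba(x1, x2))

    def test_dnn_profile_has_no_multihead_params(self):
        model = PairClassifier(ModelConfig(**{**self.CFG, "use_multihead": False}))
        assert not any(k.startswith("mha") for k in model.params)

    def test_invalid_head_count_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(**{**self.CFG, "n_heads": 3})

    def test_head_must_end_in_single_logit(self):
        with pytest.raises(ValueError, match="width 1"):
            ModelConfig(**{**self.CFG, "head_layers": (8, 4)})

    def test_probabilities_differ_between_pair_orders_only_via_attention(self, rng):
        # the element-wise-mean branch is symmetric; with attention the full
        # model may be order-sensitive, but swapping must not change F2's
        # contribution: scores of (a,b) and (b,a) agree when the attention
        # branch sees identical tokens
        model = PairClassifier(ModelConfig(**self.CFG))
        x = rng.standard_normal((3, 32))
        same = model.predict_proba(x, x)
        assert np.array_equal(same, model.predict_proba(x, x))
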